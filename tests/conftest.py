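import numpy as np
import pandas as pd
import pytest

from immunoqtl import (
    CohortGenotypes,
    AlleleTranslationTable,
    default_pool,
    encode_site_dosage,
    filter_maf,
    sample_genotypes,
    synthesize_translation_table,
)


@pytest.fixture(scope="session")
def toy_genotypes() -> CohortGenotypes:
    """Three individuals, one locus, alleles X/X, X/Y, Y/Y."""
    rows = [
        ("i1", "HLA-A", "A*01:01", "A*01:01"),
        ("i2", "HLA-A", "A*01:01", "A*02:01"),
        ("i3", "HLA-A", "A*02:01", "A*02:01"),
    ]
    return CohortGenotypes(pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"]))


@pytest.fixture(scope="session")
def triallelic_table() -> AlleleTranslationTable:
    """One SNP site where three alleles carry bases A, C, T; one monomorphic site."""
    rows = []
    for allele, base in [("A*01:01", "A"), ("A*02:01", "C"), ("A*03:01", "T")]:
        rows.append(("HLA-A", "snp", 101, allele, base))
        rows.append(("HLA-A", "snp", 202, allele, "G"))  # monomorphic
    return AlleleTranslationTable(pd.DataFrame(rows, columns=["locus", "level", "position", "allele", "symbol"]))


@pytest.fixture(scope="session")
def cohort_200():
    """A 200-individual cohort with MAF-filtered amino-acid dosages (shared, read-only)."""
    pool = default_pool(seed=11)
    genotypes = sample_genotypes(pool, 200, seed=12)
    table = synthesize_translation_table(pool, seed=13)
    aa = filter_maf(encode_site_dosage(genotypes, table, "amino_acid"))
    return pool, genotypes, table, aa
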