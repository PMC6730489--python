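import itertools

import numpy as np
import pandas as pd
import pytest

from immunoqtl import (
    AlleleTranslationTable,
    CohortGenotypes,
    DosageMatrix,
    encode_allele_dosage,
    encode_site_dosage,
    filter_maf,
    import_vcf_snp_dosage,
)
from immunoqtl.encoding import parse_variant_id


class TestAlleleDosage:
    def test_homozygote_heterozygote_and_column_sums(self, toy_genotypes):
        dm = encode_allele_dosage(toy_genotypes)
        x = dm.values["HLA-A.allele.0.A*01:01"]
        y = dm.values["HLA-A.allele.0.A*02:01"]
        assert list(x) == [2, 1, 0]
        assert list(y) == [0, 1, 2]
        assert x.sum() == 3 and y.sum() == 3
        # allele-level per-locus row sums are always two copies
        assert (dm.values.sum(axis=1) == 2).all()

    def test_missing_genotype_is_an_error(self):
        rows = [("i1", "HLA-A", "A*01:01", "A*01:01"), ("i2", "HLA-B", "B*07:02", "B*07:02")]
        g = CohortGenotypes(pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"]))
        with pytest.raises(ValueError, match="incomplete"):
            encode_allele_dosage(g)


class TestSiteDosage:
    def test_biallelic_reference_coding(self, toy_genotypes):
        """Genotypes AA / AC / CC code as 2 / 1 / 0 for reference A."""
        rows = [("HLA-A", "snp", 7, "A*01:01", "A"), ("HLA-A", "snp", 7, "A*02:01", "C")]
        table = AlleleTranslationTable(
            pd.DataFrame(rows, columns=["locus", "level", "position", "allele", "symbol"])
        )
        dm = encode_site_dosage(toy_genotypes, table, "snp")
        assert list(dm.values["HLA-A.snp.7.A"]) == [2, 1, 0]
        assert list(dm.values["HLA-A.snp.7.C"]) == [0, 1, 2]

    def test_triallelic_expands_to_three_columns(self, triallelic_table):
        rows = [
            ("i1", "HLA-A", "A*01:01", "A*01:01"),  # AA
            ("i2", "HLA-A", "A*01:01", "A*03:01"),  # AT
            ("i3", "HLA-A", "A*01:01", "A*02:01"),  # AC
            ("i4", "HLA-A", "A*03:01", "A*03:01"),  # TT
            ("i5", "HLA-A", "A*02:01", "A*02:01"),  # CC
        ]
        g = CohortGenotypes(pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"]))
        dm = encode_site_dosage(g, triallelic_table, "snp")
        site_cols = [c for c in dm.values.columns if ".101." in c]
        assert len(site_cols) == 3
        assert list(dm.values["HLA-A.snp.101.A"]) == [2, 1, 1, 0, 0]
        # monomorphic site 202 emits nothing
        assert not any(".202." in c for c in dm.values.columns)

    def test_monomorphic_cohort_yields_no_variants(self, triallelic_table):
        rows = [("i1", "HLA-A", "A*01:01", "A*01:01"), ("i2", "HLA-A", "A*01:01", "A*01:01")]
        g = CohortGenotypes(pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"]))
        dm = encode_site_dosage(g, triallelic_table, "snp")
        assert dm.n_variants == 0

    def test_unknown_allele_error_names_the_allele(self, triallelic_table):
        rows = [("i1", "HLA-A", "A*99:99", "A*01:01")]
        g = CohortGenotypes(pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"]))
        with pytest.raises(KeyError, match="A\\*99:99"):
            encode_site_dosage(g, triallelic_table, "snp")

    def test_per_site_dosages_sum_to_two(self, cohort_200):
        _, genotypes, table, _ = cohort_200
        dm = encode_site_dosage(genotypes, table, "amino_acid")
        by_site = dm.variants.groupby(["locus", "position"]).groups
        for _, ids in by_site.items():
            sums = dm.values[list(ids)].sum(axis=1)
            assert (sums == 2).all()

    def test_matches_brute_force_count_on_random_small_cohorts(self):
        """Oracle: per individual, count each symbol over the two allele-derived symbols."""
        rng = np.random.default_rng(42)
        residues = list("ILVMF")
        for trial in range(25):
            n_alleles = rng.integers(2, 6)
            alleles = [f"A*{k + 1:02d}:01" for k in range(n_alleles)]
            symbol_of = {a: residues[rng.integers(len(residues))] for a in alleles}
            table = AlleleTranslationTable(pd.DataFrame(
                [("HLA-A", "amino_acid", 9, a, s) for a, s in symbol_of.items()],
                columns=["locus", "level", "position", "allele", "symbol"],
            ))
            n = int(rng.integers(2, 11))
            pairs = [(alleles[rng.integers(n_alleles)], alleles[rng.integers(n_alleles)]) for _ in range(n)]
            g = CohortGenotypes(pd.DataFrame(
                [(f"i{j}", "HLA-A", a1, a2) for j, (a1, a2) in enumerate(pairs)],
                columns=["individual_id", "locus", "allele1", "allele2"],
            ))
            dm = encode_site_dosage(g, table, "amino_acid")
            observed_symbols = {symbol_of[a] for pair in pairs for a in pair}
            expected_cols = observed_symbols if len(observed_symbols) > 1 else set()
            assert {v.split(".")[-1] for v in dm.values.columns} == expected_cols
            for vid in dm.values.columns:
                sym = vid.split(".")[-1]
                brute = [
                    (symbol_of[a1] == sym) + (symbol_of[a2] == sym) for a1, a2 in pairs
                ]
                assert list(dm.values[vid]) == brute


class TestMafFilter:
    def test_hand_counted_examples(self):
        values = pd.DataFrame(
            {
                "HLA-A.snp.1.A": [0, 0, 0, 0, 0],       # f=0, removed
                "HLA-A.snp.2.A": [0, 0, 1, 2, 1],       # f=0.4, retained
                "HLA-A.snp.3.A": [2, 2, 2, 2, 2],       # f=1, removed
            },
            index=pd.Index([f"i{k}" for k in range(5)], name="individual_id"),
        )
        dm = DosageMatrix(values)
        kept = filter_maf(dm, 0.05)
        assert list(kept.values.columns) == ["HLA-A.snp.2.A"]

    def test_boundary_maf_exactly_at_threshold_is_retained(self):
        # 20 individuals, 2 carriers of one copy: f = 2/40 = 0.05
        col = [1, 1] + [0] * 18
        dm = DosageMatrix(pd.DataFrame({"HLA-A.snp.5.A": col},
                                       index=pd.Index([f"i{k}" for k in range(20)], name="individual_id")))
        assert filter_maf(dm, 0.05).n_variants == 1

    def test_idempotent(self, cohort_200):
        _, _, _, aa = cohort_200
        once = filter_maf(aa, 0.05)
        twice = filter_maf(once, 0.05)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_threshold_validation(self, cohort_200):
        with pytest.raises(ValueError):
            filter_maf(cohort_200[3], 0.7)


class TestRoundTripAndIds:
    def test_tsv_round_trip_bit_exact(self, cohort_200, tmp_path):
        _, _, _, aa = cohort_200
        aa.to_tsv(tmp_path / "d.tsv", tmp_path / "m.tsv")
        back = DosageMatrix.from_tsv(tmp_path / "d.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(aa.values.astype(np.int8), back.values)
        assert list(back.variants.index) == list(aa.variants.index)
        assert list(back.variants["position"]) == list(aa.variants["position"])

    @pytest.mark.parametrize(
        "vid,locus,level,position,symbol",
        [
            ("HLA-A.amino_acid.97.M", "HLA-A", "amino_acid", 97, "M"),
            ("HLA-A.I97M", "HLA-A", "amino_acid", 97, "M"),
            ("HLA-DQA1.A199T", "HLA-DQA1", "amino_acid", 199, "T"),
            ("HLA-B.allele.0.B*07:02", "HLA-B", "allele", 0, "B*07:02"),
        ],
    )
    def test_parse_variant_id(self, vid, locus, level, position, symbol):
        v = parse_variant_id(vid)
        assert (v.locus, v.level, v.position, v.ref_symbol) == (locus, level, position, symbol)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr6>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


class TestVcfImport:
    def test_biallelic_complementarity(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + "chr6\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        dm = import_vcf_snp_dosage(path)
        assert list(dm.values["chr6.snp.100.A"]) == [2, 1, 0]
        assert list(dm.values["chr6.snp.100.C"]) == [0, 1, 2]

    def test_multiallelic_record_emits_three_columns(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + "chr6\t200\t.\tA\tC,T\t.\t.\t.\tGT\t0/1\t0/2\t1/2\n")
        dm = import_vcf_snp_dosage(path)
        assert dm.n_variants == 3
        assert (dm.values.sum(axis=1) == 2).all()

    def test_missing_genotype_lists_records(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + "chr6\t300\t.\tG\tT\t.\t.\t.\tGT\t./.\t0/1\t1/1\n")
        with pytest.raises(ValueError, match="chr6:300"):
            import_vcf_snp_dosage(path)
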