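"""Encode the cohort's HLA genotypes as dosage matrices at all three levels.

Reads results/cohort/, applies the multi-allelic expansion and the MAF < 0.05
filter, and writes one dosage matrix (plus variant metadata) per level under
results/dosages/.
"""

from pathlib import Path

from immunoqtl import (
    AlleleTranslationTable,
    CohortGenotypes,
    encode_allele_dosage,
    encode_site_dosage,
    filter_maf,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    genotypes = CohortGenotypes.from_tsv(ROOT / "cohort" / "genotypes.tsv")
    table = AlleleTranslationTable.from_tsv(ROOT / "cohort" / "translation.tsv")
    out = ROOT / "dosages"
    out.mkdir(parents=True, exist_ok=True)

    for level in ("allele", "snp", "amino_acid"):
        if level == "allele":
            raw = encode_allele_dosage(genotypes)
        else:
            raw = encode_site_dosage(genotypes, table, level)
        kept = filter_maf(raw, 0.05)
        kept.to_tsv(out / f"dosage_{level}.tsv", out / f"dosage_{level}_meta.tsv")
        print(f"{level:11s}: {raw.n_variants:4d} encoded variants, "
              f"{kept.n_variants:4d} kept at MAF >= 0.05")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
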