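"""Association scan of V-gene usage against all HLA variants, per level.

Runs the linear-model scan at the allele, SNP and amino-acid levels with BH
FDR within each level, reports significant counts for the TRBV target family
versus the IGHV control family, and writes the association table, inflation
report and QQ coordinates under results/associations/.
"""

import json
from pathlib import Path

import pandas as pd

from immunoqtl import DosageMatrix, UsageMatrix, qq_lambda, scan

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> None:
    usage = UsageMatrix.from_tsv(ROOT / "cohort" / "usage.tsv", ROOT / "cohort" / "usage_meta.tsv")
    out = ROOT / "associations"
    out.mkdir(parents=True, exist_ok=True)

    frames, inflation = [], {}
    for level in ("allele", "snp", "amino_acid"):
        dm = DosageMatrix.from_tsv(
            ROOT / "dosages" / f"dosage_{level}.tsv",
            ROOT / "dosages" / f"dosage_{level}_meta.tsv",
        )
        part = scan(usage, dm, phenotype_mode="raw", fdr_threshold=0.05)
        frames.append(part)
        target = part[part["gene_id"].str.startswith("TRBV")]
        control = part[part["gene_id"].str.startswith("IGHV")]
        rep_t = qq_lambda(target["p_value"].to_numpy(), seed=SEED)
        rep_c = qq_lambda(control["p_value"].to_numpy(), seed=SEED)
        inflation[level] = {"target": rep_t.to_json_dict(), "control": rep_c.to_json_dict()}
        rep_t.qq.to_csv(out / f"qq_{level}_target.tsv", sep="\t", index=False, float_format="%.6g")
        rep_c.qq.to_csv(out / f"qq_{level}_control.tsv", sep="\t", index=False, float_format="%.6g")
        sig = part[part["significant"]]
        print(f"{level:11s}: {len(part):6d} tests | significant variants "
              f"(TRBV) {sig.loc[sig['gene_id'].str.startswith('TRBV'), 'variant_id'].nunique():3d}, "
              f"(IGHV) {sig.loc[sig['gene_id'].str.startswith('IGHV'), 'variant_id'].nunique():3d} | "
              f"lambda TRBV {rep_t.lambda_gc:.2f}, IGHV {rep_c.lambda_gc:.2f}")

    assoc = pd.concat(frames, ignore_index=True)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.12g")
    (out / "inflation.json").write_text(json.dumps(inflation, indent=1))

    aa_sig = assoc[(assoc["level"] == "amino_acid") & assoc["significant"]]
    genes = sorted(aa_sig.loc[aa_sig["gene_id"].str.startswith("TRBV"), "gene_id"].unique())
    n_target = assoc.loc[assoc["gene_id"].str.startswith("TRBV"), "gene_id"].nunique()
    print(f"TRBV genes with >=1 amino-acid association: {len(genes)}/{n_target} -> {genes}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
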