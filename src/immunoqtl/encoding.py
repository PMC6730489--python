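"""Dosage encoding of HLA genotypes at three genetic levels.

Cohort genotypes (two four-digit alleles per individual per locus) are
converted into 0/1/2 dosage matrices at the allele, SNP and amino-acid
levels. Multi-allelic sites are expanded: every observed symbol at a site in
turn plays the reference role and gets its own dosage column, so a
tri-allelic SNP yields three columns and the per-individual dosages of one
site always sum to 2 across its columns. Columns with minor allele frequency
below a threshold (strictly) are removed before association testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS = ("allele", "snp", "amino_acid")

_AA_SHORTHAND = re.compile(r"^(?P<locus>[A-Za-z0-9*:-]+)\.(?P<ref>[A-Z])(?P<pos>\d+)(?P<alt>[A-Z])$")


@dataclass(frozen=True)
class VariantDefinition:
    """One dosage column: the counted symbol at a (locus, level, position) site.

    ``ref_symbol`` is the allele name, base or residue whose copies are
    counted (0, 1 or 2) for each individual; every other symbol at the site
    is the alternative.
    """

    locus: str
    level: str
    position: int
    ref_symbol: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")

    @property
    def variant_id(self) -> str:
        return f"{self.locus}.{self.level}.{self.position}.{self.ref_symbol}"


def parse_variant_id(variant_id: str) -> VariantDefinition:
    """Parse a canonical ``locus.level.position.symbol`` id.

    The amino-acid shorthand ``LOCUS.<ref><pos><alt>`` (e.g. ``HLA-A.I97M``)
    is accepted too; the trailing residue is taken as the counted symbol.
    """
    parts = variant_id.split(".")
    if len(parts) >= 4 and parts[1] in LEVELS:
        locus, level, pos = parts[0], parts[1], int(parts[2])
        symbol = ".".join(parts[3:])
        return VariantDefinition(locus, level, pos, symbol)
    m = _AA_SHORTHAND.match(variant_id)
    if m:
        return VariantDefinition(m["locus"], "amino_acid", int(m["pos"]), m["alt"])
    raise ValueError(f"cannot parse variant id {variant_id!r}")


@dataclass
class CohortGenotypes:
    """Per-individual, per-locus unordered pairs of four-digit HLA alleles.

    ``table`` has columns individual_id, locus, allele1, allele2, one row per
    (individual, locus).
    """

    table: pd.DataFrame

    REQUIRED = ("individual_id", "locus", "allele1", "allele2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"genotype table missing columns {missing}")
        if self.table[["allele1", "allele2"]].isna().any().any():
            raise ValueError("genotype table contains missing allele calls")
        dup = self.table.duplicated(["individual_id", "locus"])
        if dup.any():
            raise ValueError("duplicate (individual, locus) genotype rows")

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.table["individual_id"]))

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.table["locus"]))

    def require_complete(self) -> None:
        """Every individual must carry a genotype at every locus."""
        counts = self.table.groupby("individual_id")["locus"].nunique()
        n_loci = len(self.loci)
        bad = counts[counts != n_loci]
        if len(bad):
            raise ValueError(
                f"incomplete genotypes for individuals {list(bad.index[:5])} "
                f"(expected {n_loci} loci)"
            )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortGenotypes":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class AlleleTranslationTable:
    """Allele -> symbol map per (locus, level, position).

    ``table`` is long-form with columns locus, level, position, allele,
    symbol: the residue carried at an amino-acid position or the base carried
    at a SNP position by each four-digit allele.
    """

    table: pd.DataFrame

    REQUIRED = ("locus", "level", "position", "allele", "symbol")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"translation table missing columns {missing}")
        bad = set(self.table["level"]) - {"snp", "amino_acid"}
        if bad:
            raise ValueError(f"translation table has unknown levels {sorted(bad)}")
        dup = self.table.duplicated(["locus", "level", "position", "allele"])
        if dup.any():
            raise ValueError("allele maps to more than one symbol at a site")

    def site_maps(self, locus: str, level: str) -> dict[int, dict[str, str]]:
        """position -> {allele -> symbol} for one locus and level."""
        sub = self.table[(self.table["locus"] == locus) & (self.table["level"] == level)]
        out: dict[int, dict[str, str]] = {}
        for pos, grp in sub.groupby("position"):
            out[int(pos)] = dict(zip(grp["allele"], grp["symbol"]))
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleTranslationTable":
        t = pd.read_csv(path, sep="\t", dtype={"position": int}, keep_default_na=False)
        return cls(t)


@dataclass
class DosageMatrix:
    """Individuals x variants integer dosages in {0,1,2} with variant metadata.

    ``values`` is indexed by individual_id with variant_id columns;
    ``variants`` is indexed by variant_id with columns locus, level,
    position, ref_symbol, in the same column order as ``values``.
    """

    values: pd.DataFrame
    variants: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variants is None:
            self.variants = pd.DataFrame(
                [parse_variant_id(v).__dict__ for v in self.values.columns],
                index=pd.Index(self.values.columns, name="variant_id"),
            )
        if list(self.values.columns) != list(self.variants.index):
            raise ValueError("values columns and variant metadata disagree")
        vals = self.values.to_numpy()
        if vals.size and not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("dosages must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def subset(self, variant_ids) -> "DosageMatrix":
        ids = list(variant_ids)
        return DosageMatrix(self.values[ids], self.variants.loc[ids])

    def to_tsv(self, path, meta_path=None) -> None:
        out = self.values.copy()
        out.index.name = "individual_id"
        out.to_csv(path, sep="\t")
        if meta_path is not None:
            self.variants.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, meta_path=None) -> "DosageMatrix":
        values = pd.read_csv(path, sep="\t", index_col="individual_id")
        variants = None
        if meta_path is not None:
            variants = pd.read_csv(meta_path, sep="\t", index_col="variant_id", keep_default_na=False)
        return cls(values.astype(np.int8), variants)


def encode_allele_dosage(genotypes: CohortGenotypes) -> DosageMatrix:
    """Count copies of each observed four-digit allele per individual.

    One variant column per distinct allele at each locus; an individual's
    dosage is the number of copies (0, 1 or 2) they carry. Requires complete
    genotypes — missing entries are an error, never imputed.
    """
    genotypes.require_complete()
    t = genotypes.table
    individuals = genotypes.individuals
    cols: dict[str, np.ndarray] = {}
    meta = []
    for locus in genotypes.loci:
        sub = t[t["locus"] == locus].set_index("individual_id").loc[individuals]
        a1, a2 = sub["allele1"].to_numpy(), sub["allele2"].to_numpy()
        for allele in sorted(set(a1) | set(a2)):
            var = VariantDefinition(locus, "allele", 0, allele)
            cols[var.variant_id] = (a1 == allele).astype(np.int8) + (a2 == allele).astype(np.int8)
            meta.append(var)
    values = pd.DataFrame(cols, index=pd.Index(individuals, name="individual_id"))
    variants = pd.DataFrame(
        [v.__dict__ for v in meta], index=pd.Index([v.variant_id for v in meta], name="variant_id")
    )
    return DosageMatrix(values, variants)


def encode_site_dosage(
    genotypes: CohortGenotypes,
    table: AlleleTranslationTable,
    level: str,
) -> DosageMatrix:
    """Expand polymorphic SNP / amino-acid sites into per-symbol dosage columns.

    At each site every symbol observed in the cohort becomes a variant that
    counts its own copies, so the homozygote for a symbol scores 2, either
    heterozygote scores 1 and non-carriers 0; a site with three bases yields
    three columns. Sites monomorphic in the cohort yield no variants.
    """
    if level not in ("snp", "amino_acid"):
        raise ValueError(f"level must be 'snp' or 'amino_acid', got {level!r}")
    genotypes.require_complete()
    t = genotypes.table
    individuals = genotypes.individuals
    cols: dict[str, np.ndarray] = {}
    meta = []
    for locus in genotypes.loci:
        site_maps = table.site_maps(locus, level)
        if not site_maps:
            continue
        sub = t[t["locus"] == locus].set_index("individual_id").loc[individuals]
        a1, a2 = sub["allele1"], sub["allele2"]
        for pos in sorted(site_maps):
            amap = site_maps[pos]
            for allele in set(a1) | set(a2):
                if allele not in amap:
                    raise KeyError(
                        f"allele {allele!r} at {locus} absent from translation table "
                        f"({level} position {pos})"
                    )
            s1 = a1.map(amap).to_numpy()
            s2 = a2.map(amap).to_numpy()
            observed = sorted(set(s1) | set(s2))
            if len(observed) < 2:
                continue  # monomorphic in this cohort
            for sym in observed:
                var = VariantDefinition(locus, level, pos, sym)
                cols[var.variant_id] = (s1 == sym).astype(np.int8) + (s2 == sym).astype(np.int8)
                meta.append(var)
    values = pd.DataFrame(cols, index=pd.Index(individuals, name="individual_id"))
    variants = pd.DataFrame(
        [v.__dict__ for v in meta], index=pd.Index([v.variant_id for v in meta], name="variant_id")
    )
    return DosageMatrix(values, variants)


def filter_maf(matrix: DosageMatrix, threshold: float = 0.05) -> DosageMatrix:
    """Drop columns with minor allele frequency strictly below ``threshold``.

    Frequency of the counted symbol is mean(dosage)/2; MAF = min(f, 1-f).
    A column sitting exactly at the threshold is retained.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must lie in [0, 0.5], got {threshold}")
    if matrix.n_variants == 0 or matrix.n_individuals == 0:
        raise ValueError("cannot MAF-filter an empty dosage matrix")
    f = matrix.values.to_numpy().mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep = [c for c, m in zip(matrix.values.columns, maf) if m >= threshold]
    return DosageMatrix(matrix.values[keep], matrix.variants.loc[keep])


def import_vcf_snp_dosage(vcf_path, region: str | None = None) -> DosageMatrix:
    """Read SNP dosages from a VCF, expanding multi-allelic records per symbol.

    Every REF/ALT base observed in the genotypes of a record becomes its own
    counted column, following the same expansion rule as
    :func:`encode_site_dosage`. Missing or half-called genotypes abort with a
    list of the offending records.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    samples = list(vf.header.samples)
    cols: dict[str, np.ndarray] = {}
    meta = []
    bad_records: list[str] = []
    records = vf.fetch(region=region) if region else vf
    for rec in records:
        symbols = np.empty((len(samples), 2), dtype=object)
        ok = True
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                bad_records.append(f"{rec.chrom}:{rec.pos}:{sample}")
                ok = False
                continue
            symbols[i, 0] = rec.alleles[gt[0]]
            symbols[i, 1] = rec.alleles[gt[1]]
        if not ok:
            continue
        observed = sorted({s for pair in symbols for s in pair})
        if len(observed) < 2:
            continue
        for sym in observed:
            var = VariantDefinition(rec.chrom, "snp", rec.pos, sym)
            cols[var.variant_id] = (symbols == sym).sum(axis=1).astype(np.int8)
            meta.append(var)
    if bad_records:
        raise ValueError(f"missing or half-called genotypes in VCF: {bad_records[:10]}")
    values = pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))
    variants = pd.DataFrame(
        [v.__dict__ for v in meta], index=pd.Index([v.variant_id for v in meta], name="variant_id")
    )
    return DosageMatrix(values, variants)
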