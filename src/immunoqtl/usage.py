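"""V-gene usage phenotypes: read proportions, zero handling, log view.

Usage of a V gene is the proportion of mapped reads assigned to it among all
mapped reads of its receptor family; genes with no supporting reads in an
individual are recorded as exactly zero. The log view is log2(usage + pseudo)
with a family-specific pseudo-usage constant (0.01 for the TCR-beta target
family, 1e-5 for the immunoglobulin heavy-chain control family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET = "target"
CONTROL = "control"

#: pseudo-usage added before log2, per gene family
PSEUDO_USAGE = {TARGET: 0.01, CONTROL: 0.00001}


@dataclass
class UsageMatrix:
    """Individuals x V-genes matrix of read proportions.

    ``values``: proportions in [0, 1], zeros marking undetected genes;
    ``family``: per-gene tag, ``target`` (TRBV-like) or ``control``
    (IGHV-like). Each gene family forms its own composition: within a family
    the detected genes of an individual sum to 1, mirroring proportions
    computed per sequencing library.
    """

    values: pd.DataFrame
    family: pd.Series = field(default=None)  # type: ignore[assignment]
    pseudo_usage: dict = field(default_factory=lambda: dict(PSEUDO_USAGE))

    def __post_init__(self) -> None:
        if self.family is None:
            self.family = pd.Series(TARGET, index=self.values.columns)
        self.family = self.family.reindex(self.values.columns)
        if self.family.isna().any():
            raise ValueError("every gene needs a family tag")
        bad = set(self.family) - {TARGET, CONTROL}
        if bad:
            raise ValueError(f"unknown family tags {sorted(bad)}")
        v = self.values.to_numpy()
        if v.size and (v < 0).any() or v.size and (v > 1).any():
            raise ValueError("usage values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def target_genes(self) -> list[str]:
        return list(self.values.columns[self.family == TARGET])

    def control_genes(self) -> list[str]:
        return list(self.values.columns[self.family == CONTROL])

    def validate_compositions(self, atol: float = 1e-6) -> None:
        """Check that detected-gene proportions sum to 1 within each family."""
        for fam in (TARGET, CONTROL):
            cols = self.values.columns[self.family == fam]
            if not len(cols):
                continue
            sums = self.values[cols].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"{fam} usage rows do not sum to 1 (max dev "
                                 f"{float(np.abs(sums - 1).max()):.3g})")

    def to_tsv(self, path, meta_path=None) -> None:
        out = self.values.copy()
        out.index.name = "individual_id"
        out.to_csv(path, sep="\t", float_format="%.12g")
        if meta_path is not None:
            meta = pd.DataFrame({"gene_id": self.values.columns, "family": self.family.values})
            meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, meta_path=None) -> "UsageMatrix":
        values = pd.read_csv(path, sep="\t", index_col="individual_id").astype(float)
        family = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t")
            family = pd.Series(meta["family"].values, index=meta["gene_id"].values)
        return cls(values, family)


def compute_usage(read_counts: pd.DataFrame, family: pd.Series | None = None) -> UsageMatrix:
    """Row-normalize nonnegative read counts into usage proportions.

    Zero counts stay exactly zero (undetected). When ``family`` is given,
    normalization runs within each family separately. An individual with no
    reads at all in a family is an error.
    """
    counts = read_counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be nonnegative")
    fam = pd.Series(TARGET, index=counts.columns) if family is None else family.reindex(counts.columns)
    values = counts.copy()
    for tag in fam.dropna().unique():
        cols = counts.columns[fam == tag]
        totals = counts[cols].sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0][:5])
            raise ValueError(f"individuals with all-zero counts in family {tag!r}: {bad}")
        values[cols] = counts[cols].div(totals, axis=0)
    return UsageMatrix(values, fam)


def log_transform(usage: UsageMatrix, pseudo: float | None = None) -> pd.DataFrame:
    """Elementwise log2(usage + pseudo-usage).

    With ``pseudo=None`` each gene uses its family's constant from
    ``usage.pseudo_usage``; a float applies one constant everywhere.
    """
    if pseudo is not None:
        if pseudo <= 0:
            raise ValueError("pseudo-usage must be positive")
        return np.log2(usage.values + pseudo)
    offsets = usage.family.map(usage.pseudo_usage).astype(float)
    if (offsets <= 0).any():
        raise ValueError("pseudo-usage must be positive")
    return np.log2(usage.values + offsets)
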