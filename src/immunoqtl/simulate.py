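"""Synthetic cohorts with the statistical structure the association analysis assumes.

The generator emulates a cord-blood cohort: ~201 individuals genotyped at the
eight classical HLA loci (allele counts per locus matching the diversity of
the study population), an allele translation table tying alleles to residues
and bases (so amino-acid and SNP variation is linked through alleles, which
induces MHC-like linkage disequilibrium by construction), and per-individual
V-gene usage for 48 TCR-beta target genes plus an immunoglobulin heavy-chain
control family. Usage is built compositionally: each gene gets a Gaussian
latent log-score (baseline + planted additive dosage effects + noise), genes
drop out at random, and the detected genes of each family are softmax
normalized — so rows are read-proportion-like compositions and dropped genes
are exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import AlleleTranslationTable, CohortGenotypes, DosageMatrix, VariantDefinition
from .usage import CONTROL, TARGET, UsageMatrix

#: allele counts per classical locus observed in the emulated cohort
DEFAULT_ALLELE_COUNTS = {
    "HLA-A": 23,
    "HLA-B": 46,
    "HLA-C": 21,
    "HLA-DRB1": 28,
    "HLA-DPB1": 16,
    "HLA-DPA1": 4,
    "HLA-DQB1": 14,
    "HLA-DQA1": 15,
}

_RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")
_BASES = list("ACGT")


@dataclass
class HaplotypePool:
    """Population allele frequencies per locus for Hardy-Weinberg sampling."""

    loci: list
    alleles_per_locus: dict

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus not in self.alleles_per_locus:
                raise ValueError(f"no alleles for locus {locus!r}")
            freqs = self.alleles_per_locus[locus]
            if len(set(freqs)) != len(freqs):
                raise ValueError(f"duplicate allele names at {locus}")
            vals = np.array(list(freqs.values()), dtype=float)
            if (vals <= 0).any():
                raise ValueError(f"non-positive allele frequency at {locus}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies at {locus} sum to {vals.sum()}, not 1")

    def alleles(self, locus: str) -> list[str]:
        return list(self.alleles_per_locus[locus])


def default_pool(seed: int = 0, allele_counts: dict | None = None) -> HaplotypePool:
    """Skewed-frequency allele pool over the eight classical HLA loci.

    Frequencies are drawn once from a symmetric Dirichlet (concentration 0.8,
    mimicking the few-common-many-rare shape of real HLA allele spectra) and
    allele names follow four-digit nomenclature (e.g. ``A*03:01``).
    """
    counts = DEFAULT_ALLELE_COUNTS if allele_counts is None else allele_counts
    rng = np.random.default_rng(seed)
    alleles_per_locus = {}
    for locus, k in counts.items():
        short = locus.replace("HLA-", "")
        names = [f"{short}*{i + 1:02d}:01" for i in range(k)]
        freqs = rng.dirichlet(np.full(k, 0.8))
        # keep strictly positive within float precision
        freqs = np.maximum(freqs, 1e-9)
        freqs = freqs / freqs.sum()
        alleles_per_locus[locus] = dict(zip(names, freqs))
    return HaplotypePool(loci=list(counts), alleles_per_locus=alleles_per_locus)


@dataclass
class EffectSpec:
    """Planted additive effects: (variant_id, gene_id, beta per dosage unit)."""

    entries: list = field(default_factory=list)

    def validate(self, dosages: DosageMatrix, target_genes: list) -> None:
        targets = set(target_genes)
        for variant_id, gene_id, _ in self.entries:
            if variant_id not in dosages.values.columns:
                raise ValueError(f"effect variant {variant_id!r} absent from dosage matrix")
            if gene_id not in targets:
                raise ValueError(
                    f"effect gene {gene_id!r} is not a target gene; control genes carry no effects"
                )


@dataclass
class SimulationConfig:
    """Cohort dimensions and noise for the usage generator.

    ``noise_sd`` is the SD of per-individual per-gene Gaussian noise on the
    latent log-score; ``dropout_rate`` the probability a gene goes undetected
    in an individual; ``baseline_concentration`` the symmetric Dirichlet
    concentration for baseline gene proportions.
    """

    n_individuals: int = 201
    n_target_genes: int = 48
    n_control_genes: int = 20
    noise_sd: float = 0.3
    dropout_rate: float = 0.02
    baseline_concentration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    def target_genes(self) -> list[str]:
        return [f"TRBV{i + 1}" for i in range(self.n_target_genes)]

    def control_genes(self) -> list[str]:
        return [f"IGHV{i + 1}" for i in range(self.n_control_genes)]


@dataclass
class GroundTruth:
    """What was planted: effects, baselines, dropout mask, config echo."""

    effects: EffectSpec
    baseline: pd.Series
    dropout: pd.DataFrame
    config: SimulationConfig

    def to_json_dict(self) -> dict:
        return {
            "effects": [list(e) for e in self.effects.entries],
            "baseline": {k: float(v) for k, v in self.baseline.items()},
            "config": {
                "n_individuals": self.config.n_individuals,
                "n_target_genes": self.config.n_target_genes,
                "n_control_genes": self.config.n_control_genes,
                "noise_sd": self.config.noise_sd,
                "dropout_rate": self.config.dropout_rate,
                "baseline_concentration": self.config.baseline_concentration,
                "seed": self.config.seed,
            },
        }


def sample_genotypes(pool: HaplotypePool, n: int, seed: int = 0) -> CohortGenotypes:
    """Draw two alleles per locus per individual i.i.d. (Hardy-Weinberg)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    individuals = [f"ind{i + 1:04d}" for i in range(n)]
    rows = []
    for locus in pool.loci:
        freqs = pool.alleles_per_locus[locus]
        names = list(freqs)
        p = np.array(list(freqs.values()))
        draws = rng.choice(len(names), size=(n, 2), p=p)
        for i, ind in enumerate(individuals):
            rows.append((ind, locus, names[draws[i, 0]], names[draws[i, 1]]))
    table = pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"])
    # one row per (individual, locus), individuals in draw order
    table = table.sort_values(["individual_id", "locus"], kind="stable").reset_index(drop=True)
    return CohortGenotypes(table)


def _partition_alleles(rng, alleles: list[str], k: int, symbols: list[str]) -> dict[str, str]:
    """Assign each allele one of k distinct symbols, every symbol used."""
    chosen = list(rng.choice(symbols, size=k, replace=False))
    order = rng.permutation(len(alleles))
    assignment = {}
    for rank, idx in enumerate(order):
        sym = chosen[rank] if rank < k else chosen[rng.integers(k)]
        assignment[alleles[idx]] = sym
    return assignment


def synthesize_translation_table(
    pool: HaplotypePool,
    n_aa_positions: int = 25,
    n_snp_positions: int = 40,
    seed: int = 0,
) -> AlleleTranslationTable:
    """Random allele -> residue/base maps with MHC-like linkage structure.

    Every allele gets one residue per amino-acid position and one base per
    SNP position. Per locus (allele count permitting) at least one position
    is polymorphic and at least one carries three or more residues; because
    alleles share symbols, positions are correlated through the allele
    spectrum exactly as real MHC amino acids are.
    """
    if n_aa_positions < 1 or n_snp_positions < 1:
        raise ValueError("need at least one position per level")
    rng = np.random.default_rng(seed)
    rows = []
    for locus in pool.loci:
        alleles = pool.alleles(locus)
        n_all = len(alleles)
        for level, n_pos, symbols, max_k, span in (
            ("amino_acid", n_aa_positions, _RESIDUES, 4, 275),
            ("snp", n_snp_positions, _BASES, 3, 1100),
        ):
            positions = np.sort(rng.choice(np.arange(1, span + 1), size=min(n_pos, span), replace=False))
            for j, pos in enumerate(positions):
                if j == 0 and n_all >= 2:
                    k = 2  # guaranteed polymorphic site
                elif j == 1 and n_all >= 3:
                    k = 3  # guaranteed multi-allelic site
                else:
                    k = int(rng.integers(1, min(max_k, n_all) + 1))
                assignment = _partition_alleles(rng, alleles, k, symbols)
                for allele in alleles:
                    rows.append((locus, level, int(pos), allele, assignment[allele]))
    table = pd.DataFrame(rows, columns=["locus", "level", "position", "allele", "symbol"])
    return AlleleTranslationTable(table)


def generate_usage(
    genotypes: CohortGenotypes,
    dosages: DosageMatrix,
    effects: EffectSpec,
    config: SimulationConfig,
) -> tuple[UsageMatrix, GroundTruth]:
    """Compositional usage with planted additive dosage effects on log-scores.

    Latent score s_ig = log(baseline_g) + sum_v beta_v * dosage_iv (for
    effects on gene g) + Normal(0, noise_sd) noise; usage row = softmax of
    s over the detected genes of each family, dropped genes exactly 0. With
    zero effects, zero noise and no dropout every row reproduces the baseline
    proportions exactly.
    """
    individuals = genotypes.individuals
    if list(dosages.values.index) != list(individuals):
        raise ValueError("dosage matrix rows do not match cohort individuals")
    genes = config.target_genes() + config.control_genes()
    family = pd.Series(
        [TARGET] * config.n_target_genes + [CONTROL] * config.n_control_genes, index=genes
    )
    effects.validate(dosages, config.target_genes())

    rng = np.random.default_rng(config.seed)
    n, G = len(individuals), len(genes)
    baseline_parts = []
    for fam in (TARGET, CONTROL):
        k = int((family == fam).sum())
        if k:
            baseline_parts.append(rng.dirichlet(np.full(k, config.baseline_concentration)))
    baseline = pd.Series(np.concatenate(baseline_parts) if baseline_parts else [], index=genes)

    s = np.tile(np.log(baseline.to_numpy()), (n, 1))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for variant_id, gene_id, beta in effects.entries:
        s[:, gene_pos[gene_id]] += beta * dosages.values[variant_id].to_numpy(dtype=float)
    if config.noise_sd > 0:
        s += rng.normal(0.0, config.noise_sd, size=(n, G))

    detected = rng.random((n, G)) >= config.dropout_rate
    values = np.zeros((n, G))
    for fam in (TARGET, CONTROL):
        cols = np.flatnonzero((family == fam).to_numpy())
        if not len(cols):
            continue
        det = detected[:, cols]
        # every individual keeps at least one detected gene per family
        empty = ~det.any(axis=1)
        if empty.any():
            best = np.argmax(s[np.ix_(empty, cols)], axis=1)
            det[empty, best] = True
            detected[:, cols] = det
        sf = s[:, cols].copy()
        sf[~det] = -np.inf
        sf -= sf.max(axis=1, keepdims=True)  # stable softmax
        ex = np.exp(sf)
        values[:, cols] = ex / ex.sum(axis=1, keepdims=True)

    usage = UsageMatrix(
        pd.DataFrame(values, index=pd.Index(individuals, name="individual_id"), columns=genes),
        family,
    )
    truth = GroundTruth(
        effects=effects,
        baseline=baseline,
        dropout=pd.DataFrame(~detected, index=usage.values.index, columns=genes),
        config=config,
    )
    return usage, truth


def ld_block(
    n: int,
    causal_freq: float,
    n_passengers: int,
    tag_r: float,
    rng,
    locus: str = "HLA-A",
    start_position: int = 1,
    level: str = "amino_acid",
    n_groups: int = 1,
    symbol: str = "A",
) -> tuple[DosageMatrix, str]:
    """One causal site plus passenger linkage groups tagging it, as dosages.

    Emulates the linkage-group structure of MHC amino-acid variation: a
    causal position (haplotypes Bernoulli(``causal_freq``), Hardy-Weinberg
    dosage) and ``n_groups`` groups of passenger positions. Each group's tag
    haplotype copies the causal haplotype with probability ``tag_r`` (so the
    dosage correlation with the causal is ~``tag_r``; ``tag_r=1`` gives
    perfect proxies) and every passenger in a group repeats the group's
    dosage column exactly, the way amino-acid positions carried by the same
    allele split are perfectly correlated. Returns (dosage matrix, causal
    variant id).
    """
    if not 0 < causal_freq < 1:
        raise ValueError("causal_freq must lie in (0, 1)")
    if not 0 <= tag_r <= 1:
        raise ValueError("tag_r must lie in [0, 1]")
    H = (rng.random((n, 2)) < causal_freq).astype(np.int8)
    causal = VariantDefinition(locus, level, start_position, symbol)
    cols = {causal.variant_id: H.sum(axis=1)}
    meta = [causal]
    pos = start_position + 1
    sizes = [n_passengers // n_groups] * n_groups
    sizes[0] += n_passengers - sum(sizes)
    for size in sizes:
        keep = rng.random((n, 2)) < tag_r
        fresh = (rng.random((n, 2)) < causal_freq).astype(np.int8)
        tag_dosage = np.where(keep, H, fresh).sum(axis=1).astype(np.int8)
        for _ in range(size):
            v = VariantDefinition(locus, level, pos, symbol)
            cols[v.variant_id] = tag_dosage
            meta.append(v)
            pos += 1
    values = pd.DataFrame(
        cols, index=pd.Index([f"ind{i + 1:04d}" for i in range(n)], name="individual_id")
    )
    variants = pd.DataFrame(
        [v.__dict__ for v in meta], index=pd.Index([v.variant_id for v in meta], name="variant_id")
    )
    return DosageMatrix(values, variants), causal.variant_id


def planted_phenotype(
    dosages: DosageMatrix,
    variant_ids: list,
    total_fraction: float,
    rng,
    weights=None,
) -> np.ndarray:
    """Gaussian phenotype whose planted dosage signal explains a set variance share.

    The signal is a weighted sum of standardized dosage columns (equal
    weights by default); noise variance is scaled to the empirical signal
    variance so the planted fraction of total variance is ``total_fraction``
    in expectation. Used for calibrating recovery of the scan, the stepwise
    selection and the variance partition against known truth.
    """
    if not 0 < total_fraction < 1:
        raise ValueError("total_fraction must lie in (0, 1)")
    D = dosages.values[list(variant_ids)].to_numpy(dtype=float)
    Z = (D - D.mean(axis=0)) / D.std(axis=0)
    w = np.full(Z.shape[1], 1.0 / np.sqrt(Z.shape[1])) if weights is None else np.asarray(weights, float)
    signal = Z @ w
    var_sig = float(signal.var())
    noise_sd = float(np.sqrt(var_sig * (1.0 - total_fraction) / total_fraction))
    return signal + rng.normal(0.0, noise_sd, size=len(signal))
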