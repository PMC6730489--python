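"""Per-variant, per-gene linear association scan with FDR and inflation diagnostics.

Each (variant, gene) pair is tested with a simple linear model of usage on
dosage (intercept + slope, no covariates): two-sided p from the t
distribution with n-2 degrees of freedom. The scan is vectorized over the
whole variant x gene grid via the centered cross-product identities, which
reproduce per-pair OLS exactly. Multiple testing is controlled per genetic
level with Benjamini-Hochberg at 5% FDR, and a genomic-control inflation
factor (median chi-square ratio) with QQ coordinates summarizes each level's
p-value distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import DosageMatrix
from .usage import UsageMatrix, log_transform

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 degree of freedom
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

_TINY_P = float(np.finfo(float).tiny)


def fit_pair(y: np.ndarray, d: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of a phenotype on a single dosage: (beta, se, t, two-sided p).

    Closed-form simple regression with intercept; df = n - 2. A perfect fit
    (zero residual) reports the smallest positive p rather than zero.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    n = len(y)
    if len(d) != n:
        raise ValueError("phenotype and dosage lengths differ")
    if n < 3:
        raise ValueError("need at least 3 observations")
    dc = d - d.mean()
    yc = y - y.mean()
    sxx = float(dc @ dc)
    if sxx == 0.0:
        raise ValueError("dosage has zero variance")
    sxy = float(dc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    sse = max(syy - beta * sxy, 0.0)
    df = n - 2
    sigma2 = sse / df
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        return beta, 0.0, float(np.inf) if beta != 0 else 0.0, _TINY_P
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return beta, se, t, max(p, _TINY_P)


def bh_fdr(p_values, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    Returns (q_values, flags) aligned with the input order; flags mark
    q <= q_threshold. Empty input yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= q_threshold


def _phenotype(usage, mode: str) -> pd.DataFrame:
    if isinstance(usage, pd.DataFrame):
        return usage  # pre-built phenotype, used as-is
    if mode == "raw":
        return usage.values
    if mode == "log2":
        return log_transform(usage)
    raise ValueError(f"phenotype_mode must be 'raw' or 'log2', got {mode!r}")


def scan(
    usage: UsageMatrix,
    dosages: DosageMatrix,
    phenotype_mode: str = "raw",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every (variant, gene) pair; BH-adjust within each genetic level.

    Individuals are matched by id (inner join); an empty intersection is an
    error. Variants with zero dosage variance in the joined cohort are
    skipped with a logged reason. Returns the association table with columns
    variant_id, gene_id, beta, se, t_stat, p_value, q_value, significant,
    level, n_used.
    """
    pheno = _phenotype(usage, phenotype_mode)
    common = pheno.index.intersection(dosages.values.index)
    if len(common) == 0:
        raise ValueError("no individuals shared between usage and dosage matrices")
    Y = pheno.loc[common].to_numpy(dtype=float)
    D = dosages.values.loc[common].to_numpy(dtype=float)
    n = len(common)
    if n < 3:
        raise ValueError("need at least 3 shared individuals")

    Dc = D - D.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = (Dc * Dc).sum(axis=0)
    keep = sxx > 0
    dropped = list(dosages.values.columns[~keep])
    if dropped:
        logger.info("skipping %d zero-variance variants: %s%s", len(dropped),
                    dropped[:5], "..." if len(dropped) > 5 else "")
    Dc = Dc[:, keep]
    sxx = sxx[keep]
    variant_ids = dosages.values.columns[keep]
    levels = dosages.variants.loc[variant_ids, "level"].to_numpy()

    syy = (Yc * Yc).sum(axis=0)
    sxy = Dc.T @ Yc  # variants x genes
    beta = sxy / sxx[:, None]
    sse = np.maximum(syy[None, :] - beta * sxy, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx[:, None])
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), _TINY_P)

    genes = list(pheno.columns)
    table = pd.DataFrame(
        {
            "variant_id": np.repeat(variant_ids, len(genes)),
            "gene_id": np.tile(genes, len(variant_ids)),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "t_stat": t.ravel(),
            "p_value": p.ravel(),
            "level": np.repeat(levels, len(genes)),
            "n_used": n,
        }
    )
    table["q_value"] = np.nan
    table["significant"] = False
    for _, idx in table.groupby("level").groups.items():
        q, flags = bh_fdr(table.loc[idx, "p_value"].to_numpy(), fdr_threshold)
        table.loc[idx, "q_value"] = q
        table.loc[idx, "significant"] = flags
    cols = ["variant_id", "gene_id", "beta", "se", "t_stat", "p_value",
            "q_value", "significant", "level", "n_used"]
    return table[cols]


@dataclass
class InflationReport:
    """Genomic-control inflation factor with QQ coordinates.

    ``lambda_gc`` is the median of the chi-square statistics implied by the
    p-values divided by the null chi-square median (~0.4549); ``ci95`` is a
    seeded bootstrap interval. ``qq`` pairs expected with observed
    -log10 p for plotting.
    """

    lambda_gc: float
    ci95: tuple[float, float]
    n_tests: int
    qq: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "lambda": self.lambda_gc,
            "ci95": list(self.ci95),
            "n_tests": self.n_tests,
        }


def qq_lambda(p_values, n_boot: int = 200, seed: int = 0) -> InflationReport:
    """Inflation factor and QQ coordinates for a vector of p-values.

    lambda = median(qchisq(1 - p, df=1)) / qchisq(0.5, df=1); exactly 1 when
    all p = 0.5, ~1 under the uniform null. Zero p-values are clamped to the
    smallest positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("clamping %d zero p-values for inflation estimate", int((p == 0).sum()))
        p = np.maximum(p, _TINY_P)
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    rng = np.random.default_rng(seed)
    boots = np.array([
        np.median(rng.choice(chi2, size=chi2.size, replace=True)) / CHI2_MEDIAN_1DF
        for _ in range(n_boot)
    ])
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    m = p.size
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected_minus_log10_p": exp, "observed_minus_log10_p": obs})
    return InflationReport(lam, ci, int(m), qq)
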