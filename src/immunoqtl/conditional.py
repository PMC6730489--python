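"""Forward stepwise conditional regression to independent association signals.

The MHC's extreme linkage disequilibrium means a gene's many marginally
significant variants typically tag few causal sites. Starting from the
FDR-significant candidates of one gene, the procedure selects the variant
with the smallest marginal p, then repeatedly refits every remaining
candidate with all selected variants as covariates, admitting the candidate
with the smallest conditional p while that p stays below alpha (entry at
exactly alpha is rejected). Candidates numerically collinear with the
selected set are excluded at that step. Ties on p break lexicographically by
variant id, making the procedure deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import DosageMatrix

logger = logging.getLogger(__name__)

#: relative tolerance below which a candidate's residual against the selected
#: span is treated as zero (rank-deficiency guard)
COLLINEARITY_RTOL = 1e-10


@dataclass
class ConditionalSignals:
    """Ordered independent signals for one gene.

    ``signals`` rows: step, variant_id, marginal_p, conditional_p (at entry;
    equals marginal_p for the first signal). ``stopping_reason`` is one of
    'no_candidate_below_alpha', 'candidates_exhausted',
    'all_remaining_collinear', 'degrees_of_freedom_exhausted'.
    """

    gene_id: str
    signals: pd.DataFrame
    stopping_reason: str
    alpha: float = 0.05

    @property
    def variant_ids(self) -> list[str]:
        return list(self.signals["variant_id"])

    def to_frame(self) -> pd.DataFrame:
        out = self.signals.copy()
        out.insert(0, "gene_id", self.gene_id)
        out["stopping_reason"] = self.stopping_reason
        return out


def _conditional_pvalues(y: np.ndarray, D: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope p-value of each column of D in a model with covariate basis Q.

    Q is an orthonormal basis of the current design (intercept + selected
    signals). By Frisch-Waugh-Lovell the conditional slope test equals the
    simple regression of the Q-residual of y on the Q-residual of each
    candidate, with df = n - ncol(Q) - 1. Returns (p, collinear_mask).
    """
    n = len(y)
    ry = y - Q @ (Q.T @ y)
    RD = D - Q @ (Q.T @ D)
    sxx = (RD * RD).sum(axis=0)
    norms = np.sqrt((D * D).sum(axis=0))
    collinear = np.sqrt(np.maximum(sxx, 0.0)) <= COLLINEARITY_RTOL * np.maximum(norms, 1.0)
    df = n - Q.shape[1] - 1
    if df < 1:
        raise ValueError("not enough observations for another conditional step")
    syy = float(ry @ ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = RD.T @ y
        beta = sxy / sxx
        sse = np.maximum(syy - beta * sxy, 0.0)
        t = beta / np.sqrt(sse / df / sxx)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)
    p[collinear] = np.nan
    return p, collinear


def conditional_scan(
    y,
    candidates: DosageMatrix,
    alpha: float = 0.05,
    gene_id: str = "",
) -> ConditionalSignals:
    """Forward stepwise selection of independent signals for one phenotype.

    ``y`` is the gene's phenotype indexed like the candidate dosage rows (a
    pandas Series is aligned by id; an array must already match). The
    candidate matrix should be restricted to this gene's FDR-significant
    variants from the marginal scan.
    """
    if candidates.n_variants == 0:
        raise ValueError("candidate set is empty")
    if isinstance(y, pd.Series):
        if not y.index.equals(candidates.values.index):
            y = y.reindex(candidates.values.index)
            if y.isna().any():
                raise ValueError("phenotype and candidate individuals do not align")
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        if len(yv) != candidates.n_individuals:
            raise ValueError("phenotype and candidate individuals do not align")
    n = len(yv)
    D = candidates.values.to_numpy(dtype=float)
    ids = np.array(candidates.values.columns)

    # step 0: marginal p for every candidate (intercept-only covariate basis)
    Q = np.full((n, 1), 1.0 / np.sqrt(n))
    marginal_p, collinear = _conditional_pvalues(yv, D, Q)
    marginal_by_id = dict(zip(ids, marginal_p))

    selected: list[int] = []
    rows = []
    remaining = np.ones(len(ids), dtype=bool)
    reason = "candidates_exhausted"
    step = 0
    current_p = marginal_p.copy()
    cur_collinear = collinear
    while remaining.any():
        usable = remaining & ~cur_collinear
        if not usable.any():
            reason = "all_remaining_collinear"
            break
        # smallest conditional p, ties broken by variant id
        order = np.lexsort((ids, np.where(usable, current_p, np.inf)))
        best = order[0]
        best_p = current_p[best]
        if step > 0 and not best_p < alpha:
            reason = "no_candidate_below_alpha"
            break
        rows.append(
            {
                "step": step,
                "variant_id": ids[best],
                "marginal_p": float(marginal_by_id[ids[best]]),
                "conditional_p": float(best_p),
            }
        )
        selected.append(best)
        remaining[best] = False
        if not remaining.any():
            reason = "candidates_exhausted"
            break
        X = np.column_stack([np.ones(n), D[:, selected]])
        Q, _ = np.linalg.qr(X)
        if n - Q.shape[1] - 1 < 1:
            reason = "degrees_of_freedom_exhausted"
            break
        current_p, cur_collinear = _conditional_pvalues(yv, D, Q)
        step += 1

    signals = pd.DataFrame(rows, columns=["step", "variant_id", "marginal_p", "conditional_p"])
    return ConditionalSignals(gene_id=gene_id, signals=signals, stopping_reason=reason, alpha=alpha)


def conditional_scan_all(
    usage_values: pd.DataFrame,
    dosages: DosageMatrix,
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    level: str = "amino_acid",
) -> pd.DataFrame:
    """Run the stepwise scan for every gene with FDR-significant variants.

    ``assoc`` is the marginal association table; candidates for each gene are
    its significant variants at the requested level, pooled across loci.
    Returns the concatenated per-gene signal tables.
    """
    sig = assoc[(assoc["significant"]) & (assoc["level"] == level)]
    frames = []
    for gene, grp in sig.groupby("gene_id"):
        cand_ids = sorted(grp["variant_id"].unique())
        cands = dosages.subset(cand_ids)
        common = usage_values.index.intersection(cands.values.index)
        result = conditional_scan(
            usage_values.loc[common, gene],
            DosageMatrix(cands.values.loc[common], cands.variants),
            alpha=alpha,
            gene_id=str(gene),
        )
        frames.append(result.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "step", "variant_id", "marginal_p", "conditional_p", "stopping_reason"]
        )
    return pd.concat(frames, ignore_index=True)
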