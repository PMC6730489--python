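"""Fraction of V-gene usage variance explained by independent MHC signals.

Each gene's independent signals (from conditional fine-mapping) are scored
two ways: the adjusted R² of the single-predictor model for each signal
alone, and the adjusted R² of the joint multiple regression with all signals.
With correlated predictors the single-signal values need not sum to the joint
value. Overall model significance is an F-test, BH-adjusted across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import bh_fdr
from .conditional import ConditionalSignals
from .encoding import DosageMatrix


def adjusted_r2(y, X, column_names=None) -> tuple[float, float, float, float]:
    """OLS fit with intercept: (R², adjusted R², F statistic, F p-value).

    ``X`` is one or more predictor columns; adjusted R² =
    1 - (1 - R²)(n - 1)/(n - p - 1). Rank-deficient predictors are an error
    naming the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(y):
        raise ValueError("y and X row counts differ")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    if rank < p + 1:
        names = list(column_names) if column_names is not None else list(range(p))
        # identify columns lying in the span of the preceding ones
        dependent = []
        for j in range(p):
            sub = np.column_stack([np.ones(n), X[:, : j + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                dependent.append(names[j])
        raise ValueError(f"rank-deficient design; dependent columns: {dependent}")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return (
        float(model.rsquared),
        float(model.rsquared_adj),
        float(model.fvalue),
        float(model.f_pvalue),
    )


def partition(y, signals: ConditionalSignals, dosages: DosageMatrix) -> dict:
    """Per-signal and combined adjusted R² for one gene's independent signals.

    Per-signal attribution is the adjusted R² of that signal's
    single-predictor model; the combined value refits all signals jointly.
    For a single-signal gene the combined value equals the top value.
    """
    ids = signals.variant_ids
    if not ids:
        raise ValueError(f"no signals for gene {signals.gene_id!r}")
    missing = [v for v in ids if v not in dosages.values.columns]
    if missing:
        raise KeyError(f"signals absent from dosage matrix: {missing}")
    if isinstance(y, pd.Series):
        y = y.reindex(dosages.values.index).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    per_signal = {}
    for vid in ids:
        _, adj, _, _ = adjusted_r2(y, dosages.values[vid].to_numpy(dtype=float))
        per_signal[vid] = adj
    X = dosages.values[ids].to_numpy(dtype=float)
    r2, adj, fstat, fp = adjusted_r2(y, X, column_names=ids)
    return {
        "gene_id": signals.gene_id,
        "signal_ids": list(ids),
        "per_signal_adj_r2": per_signal,
        "combined_r2": r2,
        "combined_adj_r2": adj,
        "f_stat": fstat,
        "f_p": fp,
    }


def variance_report(
    usage_values: pd.DataFrame,
    signal_table: pd.DataFrame,
    dosages: DosageMatrix,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Tabulate variance explained for every gene with at least one signal.

    ``signal_table`` is the concatenated conditional output (gene_id, step,
    variant_id, ...). Columns mirror the usual reporting layout: top and
    second signal ids, % variance explained by each alone and by all signals
    jointly, overall F p and a flag for significance at ``fdr_threshold`` FDR
    across genes (BH).
    """
    rows = []
    for gene, grp in signal_table.groupby("gene_id", sort=True):
        grp = grp.sort_values("step")
        sig = ConditionalSignals(gene_id=str(gene), signals=grp, stopping_reason="")
        common = usage_values.index.intersection(dosages.values.index)
        res = partition(
            usage_values.loc[common, gene],
            sig,
            DosageMatrix(dosages.values.loc[common], dosages.variants),
        )
        ids = res["signal_ids"]
        per = res["per_signal_adj_r2"]
        rows.append(
            {
                "gene_id": gene,
                "top_signal": ids[0],
                "second_signal": ids[1] if len(ids) > 1 else None,
                "n_signals": len(ids),
                "pct_top": 100.0 * per[ids[0]],
                "pct_second": 100.0 * per[ids[1]] if len(ids) > 1 else np.nan,
                "pct_combined": 100.0 * res["combined_adj_r2"],
                "f_p": res["f_p"],
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["gene_id", "top_signal", "second_signal", "n_signals",
                 "pct_top", "pct_second", "pct_combined", "f_p"],
    )
    if len(report):
        q, flags = bh_fdr(report["f_p"].to_numpy(), fdr_threshold)
        report["f_q"] = q
        report["significant"] = flags
    else:
        report["f_q"] = pd.Series(dtype=float)
        report["significant"] = pd.Series(dtype=bool)
    return report
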