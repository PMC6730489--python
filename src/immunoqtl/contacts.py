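"""TCR-pMHC structural contact frequencies and the association overlay.

Solved TCR-pMHC complexes provide, per structure, which MHC amino-acid
positions touch the TCR beta-chain V region or the presented peptide. The
contact frequency of a position is the fraction of a locus's complexes in
which it is contacted at least once (presence semantics — duplicate contact
rows for a complex do not count twice). The overlay joins these frequencies
with the strongest association signal (-log10 of the minimum p across genes)
at each amino-acid position, the comparison behind interface-enrichment
plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PARTNERS = ("tcr_beta_v", "peptide")


def contact_frequency(records: pd.DataFrame, complex_roster: pd.DataFrame) -> pd.DataFrame:
    """Per (locus, position, partner) contact frequency across complexes.

    ``records`` columns: complex_id, locus, position, partner; ``complex_roster``
    columns: locus, complex_id (all analyzed structures per locus, contacted
    or not). Returns rows for every observed position x both partners, with
    n_complexes_with_contact, n_complexes_total and frequency; positions
    never contacted by one partner get frequency 0 for it.
    """
    for col in ("complex_id", "locus", "position", "partner"):
        if col not in records.columns:
            raise ValueError(f"contact records missing column {col!r}")
    bad = set(records["partner"]) - set(PARTNERS)
    if bad:
        raise ValueError(f"unknown contact partners {sorted(bad)}; expected {PARTNERS}")
    roster = complex_roster.drop_duplicates()
    roster_sets = {loc: set(g["complex_id"]) for loc, g in roster.groupby("locus")}
    unknown = [
        f"{r.locus}:{r.complex_id}"
        for r in records.itertuples()
        if r.complex_id not in roster_sets.get(r.locus, set())
    ]
    if unknown:
        raise KeyError(f"contact records reference complexes absent from roster: {unknown[:10]}")

    dedup = records.drop_duplicates(["complex_id", "locus", "position", "partner"])
    rows = []
    for locus, grp in dedup.groupby("locus"):
        total = len(roster_sets[locus])
        positions = sorted(grp["position"].unique())
        counts = grp.groupby(["position", "partner"])["complex_id"].nunique()
        for pos in positions:
            for partner in PARTNERS:
                n = int(counts.get((pos, partner), 0))
                rows.append(
                    {
                        "locus": locus,
                        "position": int(pos),
                        "partner": partner,
                        "n_complexes_with_contact": n,
                        "n_complexes_total": total,
                        "frequency": n / total,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["locus", "position", "partner", "n_complexes_with_contact",
                 "n_complexes_total", "frequency"],
    )


def overlay(assoc: pd.DataFrame, profile: pd.DataFrame) -> pd.DataFrame:
    """Join association strength with contact frequencies per MHC position.

    ``assoc`` must carry amino-acid-level rows (variant_id, gene_id, p_value,
    level); the summary per (locus, position) is -log10 of the minimum p
    across genes and expanded symbols. Positions present on only one side are
    kept with nulls on the other, so nothing is silently dropped.
    """
    if len(assoc):
        aa = assoc[assoc["level"] == "amino_acid"].copy()
        from .encoding import parse_variant_id

        parsed = [parse_variant_id(v) for v in aa["variant_id"]]
        aa["locus"] = [v.locus for v in parsed]
        aa["position"] = [v.position for v in parsed]
        summary = (
            aa.groupby(["locus", "position"])["p_value"].min().rename("min_p").reset_index()
        )
        summary["minus_log10_p"] = -np.log10(summary["min_p"])
        summary = summary[["locus", "position", "minus_log10_p"]]
    else:
        summary = pd.DataFrame(columns=["locus", "position", "minus_log10_p"])

    wide = profile.pivot_table(
        index=["locus", "position"], columns="partner", values="frequency", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    for partner in PARTNERS:
        if partner not in wide.columns:
            wide[partner] = np.nan
    wide = wide.rename(columns={"tcr_beta_v": "freq_tcr_beta_v", "peptide": "freq_peptide"})

    merged = summary.merge(wide, on=["locus", "position"], how="outer")
    merged = merged.sort_values(["locus", "position"]).reset_index(drop=True)
    return merged[["locus", "position", "minus_log10_p", "freq_tcr_beta_v", "freq_peptide"]]
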