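"""Cohort characteristics table: counts by tissue compartment.

The bundled table records the composition of the 96-ROI NSCLC tissue
microarray cohort that the package's default simulation design mirrors:
per-compartment ROI counts and categorical clinical counts (sex, T stage,
N stage). Percentages are derived quantities and are therefore always
recomputed from the counts, using the same display rounding convention as
clinical summary tables (one decimal below 10%, integers otherwise, ties
to even).
"""

from __future__ import annotations

import pandas as pd

_GROUPS = ("Overall", "NAT", "TME", "Tumour")

# counts per (characteristic, level): Overall, NAT, TME, Tumour
_COHORT_COUNTS = [
    ("roi", "total", 96, 19, 32, 45),
    ("sex", "F", 42, 9, 12, 21),
    ("sex", "M", 54, 10, 20, 24),
    ("t_stage", "0", 19, 19, 0, 0),
    ("t_stage", "1", 24, 0, 11, 13),
    ("t_stage", "2", 34, 0, 15, 19),
    ("t_stage", "3", 12, 0, 4, 8),
    ("t_stage", "4", 7, 0, 2, 5),
    ("n_stage", "0", 78, 19, 23, 36),
    ("n_stage", "1", 13, 0, 6, 7),
    ("n_stage", "2", 3, 0, 2, 1),
    ("n_stage", "3", 2, 0, 1, 1),
]


def cohort_counts() -> pd.DataFrame:
    """Raw per-compartment counts for each characteristic level."""
    return pd.DataFrame(
        _COHORT_COUNTS,
        columns=["characteristic", "level", "Overall", "NAT", "TME", "Tumour"],
    )


def display_percent(count: int, total: int) -> float:
    """Clinical-table percentage rounding: one decimal below 10%, integer
    otherwise; round-half-to-even (Python's built-in round)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    return round(pct, 1) if pct < 10 else float(round(pct))


def summarize_cohort(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute group totals and display percentages from the raw counts.

    Returns one row per (characteristic, level, group) with ``count``,
    ``total`` (the group's ROI total) and ``percent``.
    """
    if counts is None:
        counts = cohort_counts()
    totals = counts.loc[counts["characteristic"] == "roi", _GROUPS].iloc[0]
    # the overall total must equal the sum of the compartment totals
    derived_overall = int(totals[["NAT", "TME", "Tumour"]].sum())
    rows = []
    rows.append({"characteristic": "roi", "level": "total", "group": "Overall",
                 "count": derived_overall, "total": derived_overall,
                 "percent": 100.0})
    for _, rec in counts[counts["characteristic"] != "roi"].iterrows():
        for group in _GROUPS:
            total = int(totals[group])
            rows.append({
                "characteristic": rec["characteristic"],
                "level": rec["level"],
                "group": group,
                "count": int(rec[group]),
                "total": total,
                "percent": display_percent(int(rec[group]), total),
            })
    return pd.DataFrame(rows)
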