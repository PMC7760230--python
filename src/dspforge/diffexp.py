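"""Compartment differential expression and within-compartment correlation.

Matched compartments (same patient profiled in both) are compared by
paired t-tests on log2 expression; unmatched compartments by Mann-Whitney
rank tests at ROI level. Each comparison panel is corrected separately by
Benjamini-Hochberg. When a patient contributes several ROIs of one
compartment, their values are averaged before pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix, log2_transform

logger = logging.getLogger("dspforge")


class DiffexpError(ValueError):
    pass


# ---------------------------------------------------------------------------
# test primitives

def paired_t(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test of per-pair differences a_i - b_i.

    Returns ``(t, df, p)``; zero-variance differences give ``(nan, df, nan)``
    with a warning (the test statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DiffexpError("paired_t requires aligned vectors")
    d = a - b
    n = d.size
    if n < 2:
        raise DiffexpError("paired_t requires >=2 complete pairs")
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        logger.warning("paired differences have zero variance; t undefined")
        return float("nan"), df, float("nan")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for the first sample.

    U counts pairs (a_i > b_j) with midrank credit for ties. The exact null
    distribution is used for small tie-free samples; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise DiffexpError("mann_whitney requires non-empty groups")
    if np.ptp(np.concatenate([a, b])) == 0:
        logger.warning("all values identical across groups; p = 1")
        return a.size * b.size / 2.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are excluded from the family size m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise DiffexpError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# comparisons

def _log2_values(norm: NormalizedMatrix | pd.DataFrame, use_log2: bool) -> pd.DataFrame:
    if isinstance(norm, NormalizedMatrix):
        if use_log2 and not norm.log2:
            return log2_transform(norm).values
        return norm.values
    return log2_transform(norm).values if use_log2 else norm


def parse_comparison(comparison) -> tuple[str, str]:
    if isinstance(comparison, str):
        parts = comparison.split("_vs_") if "_vs_" in comparison else comparison.split(":")
        if len(parts) != 2:
            raise DiffexpError(
                f"cannot parse comparison {comparison!r}; use 'A_vs_B' or 'A:B'")
        return parts[0], parts[1]
    a, b = comparison
    return a, b


def patient_compartment_means(values: pd.DataFrame,
                              roi_table: pd.DataFrame) -> pd.DataFrame:
    """Average expression per (patient, compartment); unmatched ROIs
    (no patient id) are dropped."""
    meta = roi_table.set_index("roi_id").reindex(values.index)
    keyed = values.copy()
    keyed["__patient"] = meta["patient_id"].to_numpy()
    keyed["__compartment"] = meta["compartment"].to_numpy()
    keyed = keyed.dropna(subset=["__patient"])
    return keyed.groupby(["__patient", "__compartment"], sort=True).mean()


def run_comparison(norm, roi_table: pd.DataFrame, comparison,
                   design: str = "paired", probes=None,
                   use_log2: bool = True) -> pd.DataFrame:
    """Per-probe differential expression for one compartment comparison.

    Returns one row per probe: effect (mean paired log2 difference, or
    difference of group medians for unpaired), the t or U statistic, raw
    and BH-adjusted two-sided p (adjusted within this comparison only),
    and group sizes.
    """
    comp_a, comp_b = parse_comparison(comparison)
    label = f"{comp_a}_vs_{comp_b}"
    values = _log2_values(norm, use_log2)
    if probes is not None:
        values = values[[p for p in probes if p in values.columns]]
    meta = roi_table.set_index("roi_id").reindex(values.index)

    rows = []
    if design == "paired":
        pc = patient_compartment_means(values, roi_table)
        have = pc.index.get_level_values(1)
        pts_a = set(pc.index[have == comp_a].get_level_values(0))
        pts_b = set(pc.index[have == comp_b].get_level_values(0))
        paired_pts = sorted(pts_a & pts_b)
        if len(paired_pts) < 2:
            logger.warning("comparison %s: <2 complete pairs; empty result", label)
            return _empty_result()
        a = pc.loc[[(p, comp_a) for p in paired_pts]].to_numpy()
        b = pc.loc[[(p, comp_b) for p in paired_pts]].to_numpy()
        for j, probe in enumerate(pc.columns):
            t, _df, p = paired_t(a[:, j], b[:, j])
            rows.append((probe, label, "paired", len(paired_pts), len(paired_pts),
                         float(np.mean(a[:, j] - b[:, j])), t, p))
    elif design == "unpaired":
        in_a = meta["compartment"] == comp_a
        in_b = meta["compartment"] == comp_b
        if in_a.sum() < 1 or in_b.sum() < 1:
            logger.warning("comparison %s: empty group; empty result", label)
            return _empty_result()
        va = values.loc[in_a.to_numpy()]
        vb = values.loc[in_b.to_numpy()]
        for probe in values.columns:
            u, p = mann_whitney(va[probe], vb[probe])
            effect = float(va[probe].median() - vb[probe].median())
            rows.append((probe, label, "unpaired", len(va), len(vb), effect, u, p))
    else:
        raise DiffexpError(f"unknown design {design!r}; use 'paired' or 'unpaired'")

    out = pd.DataFrame(rows, columns=["probe_id", "comparison", "design",
                                      "n_a", "n_b", "effect", "statistic", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"])
    return out


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(columns=["probe_id", "comparison", "design", "n_a",
                                 "n_b", "effect", "statistic", "p_raw", "p_adj"])


# ---------------------------------------------------------------------------
# within-compartment correlation

@dataclass
class CorrelationMatrix:
    compartment: str
    r: pd.DataFrame = field(repr=False)
    p: pd.DataFrame = field(repr=False)
    n: int = 0
    significant: pd.DataFrame = field(repr=False, default=None)
    alpha: float = 0.001


def correlation_matrix(norm, roi_table: pd.DataFrame, compartment: str,
                       probes=None, alpha: float = 0.001,
                       use_log2: bool = True) -> CorrelationMatrix:
    """Pairwise probe-probe Pearson correlation over one compartment's ROIs,
    with two-sided p from the t transform and a significance mask at
    ``p <= alpha``. Constant probes yield NA rows/columns."""
    values = _log2_values(norm, use_log2)
    if probes is not None:
        values = values[[p for p in probes if p in values.columns]]
    meta = roi_table.set_index("roi_id").reindex(values.index)
    sub = values.loc[(meta["compartment"] == compartment).to_numpy()]
    n = len(sub)
    if n < 3:
        raise DiffexpError(f"compartment {compartment!r} has {n} ROIs; need >=3")
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("constant probe(s) in %s correlation: %s", compartment,
                       list(sub.columns[constant]))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    np.fill_diagonal(p, np.nan)
    cols = sub.columns
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df <= alpha) & r_df.notna()
    return CorrelationMatrix(compartment=compartment, r=r_df, p=p_df, n=n,
                             significant=sig, alpha=alpha)
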