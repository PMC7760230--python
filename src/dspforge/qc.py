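"""Raw-count QC and isotype-IgG signal-to-noise probe robustness filtering.

Each probe's counts are divided by the mean isotype-IgG count of its ROI;
a per-probe summary (median by default) of these ratios across ROIs is
compared with a threshold (default 1.0: signal at or below background is
not robust). Target probes failing the threshold are filtered; IgG controls
and housekeepers always pass through because downstream normalization and
reporting need them. Background subtraction is deliberately not offered —
for targets expressed near background it removes signal, not noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import ProbePanel

logger = logging.getLogger("dspforge")

SUMMARY_METHODS = ("median", "mean")


class QcError(ValueError):
    pass


@dataclass
class RoiQcReport:
    """Per-ROI median raw counts with a low-count flag (advisory only)."""

    medians: pd.Series = field(repr=False)
    low_count_flag: pd.Series = field(repr=False)
    flag_threshold: float = 50.0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "median_count": self.medians,
            "low_count_flag": self.low_count_flag,
        }).rename_axis("roi_id")


@dataclass
class SnrTable:
    """IgG-relative ratios per (ROI, probe) and the per-probe robustness call."""

    ratios: pd.DataFrame = field(repr=False)   # ROIs x probes
    summary: pd.Series = field(repr=False)     # per probe
    robust: pd.Series = field(repr=False)      # per probe (controls always True)
    summary_method: str = "median"
    threshold: float = 1.0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snr_summary": self.summary,
            "robust": self.robust,
            "summary_method": self.summary_method,
            "threshold": self.threshold,
        }).rename_axis("probe_id")


def roi_median_counts(counts: pd.DataFrame, flag_threshold: float = 50.0) -> RoiQcReport:
    """Median raw count per ROI over all probes (controls included).

    ROIs below ``flag_threshold`` are flagged, never removed automatically.
    """
    if counts.empty:
        raise QcError("count matrix is empty")
    med = counts.median(axis=1)
    flags = med < flag_threshold
    if flags.any():
        logger.warning("low median count for ROI(s): %s",
                       med.index[flags].tolist())
    return RoiQcReport(medians=med, low_count_flag=flags,
                       flag_threshold=flag_threshold)


def igg_background(counts: pd.DataFrame, panel: ProbePanel) -> pd.Series:
    """Arithmetic mean of isotype-IgG control counts within each ROI.

    ROIs with a zero IgG mean are dropped (returned Series excludes them)
    with a logged warning; they cannot support a signal-to-noise ratio.
    """
    igg = panel.igg_controls
    if not igg:
        raise QcError("panel has no igg_control probes")
    present = [p for p in igg if p in counts.columns]
    if not present:
        raise QcError("no igg_control probe columns found in count matrix")
    bg = counts[present].mean(axis=1)
    zero = bg <= 0
    if zero.any():
        logger.warning("zero IgG background; ROI(s) excluded from SNR: %s",
                       bg.index[zero].tolist())
        bg = bg[~zero]
    return bg.rename("igg_background")


def snr(counts: pd.DataFrame, panel: ProbePanel,
        summary_method: str = "median", threshold: float = 1.0) -> SnrTable:
    """Per-probe signal relative to IgG background, summarized across ROIs.

    ``robust`` is ``summary >= threshold`` for target probes; IgG controls
    and housekeepers are summarized but reported non-filterable (always
    robust) because downstream stages need them.
    """
    if threshold <= 0:
        raise QcError("snr threshold must be > 0")
    if summary_method not in SUMMARY_METHODS:
        raise QcError(f"summary_method must be one of {SUMMARY_METHODS}")
    bg = igg_background(counts, panel)
    ratios = counts.loc[bg.index].div(bg, axis=0)
    summary = ratios.median(axis=0) if summary_method == "median" else ratios.mean(axis=0)
    is_target = pd.Series(
        [panel.probe_class(p) == "target" if p in panel else True
         for p in counts.columns], index=counts.columns)
    robust = (summary >= threshold) | ~is_target
    return SnrTable(ratios=ratios, summary=summary, robust=robust,
                    summary_method=summary_method, threshold=threshold)


def filter_probes(snr_table: SnrTable, panel: ProbePanel) -> list[str]:
    """Robust target probes plus all controls, in panel order."""
    robust = snr_table.robust
    kept_targets = [p for p in panel.targets
                    if p in robust.index and robust[p]]
    if not kept_targets:
        raise QcError(
            "no target probe passes the signal-to-noise threshold "
            f"({snr_table.threshold}); review the threshold or the data")
    dropped = [p for p in panel.targets if p in robust.index and not robust[p]]
    if dropped:
        logger.info("filtered %d probe(s) below SNR threshold: %s",
                    len(dropped), dropped)
    passthrough = [p for p in panel.probe_ids
                   if panel.probe_class(p) != "target" and p in robust.index]
    ordered = [p for p in panel.probe_ids if p in set(kept_targets) | set(passthrough)]
    return ordered


class SnrProbeFilter(BaseEstimator, TransformerMixin):
    """Feature filter dropping target probes with poor IgG-relative signal.

    Parameters
    ----------
    panel : ProbePanel
        Probe annotation giving each column's class.
    summary : {"median", "mean"}, default "median"
        Across-ROI summary of the per-ROI IgG-relative ratios.
    threshold : float, default 1.0
        Robustness cutoff on the summary; 1.0 means "at background".

    Attributes
    ----------
    snr_ : SnrTable
    kept_probes_ : list of str
        Robust targets plus controls, in panel order.
    """

    def __init__(self, panel: ProbePanel, summary: str = "median",
                 threshold: float = 1.0):
        self.panel = panel
        self.summary = summary
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "SnrProbeFilter":
        X = _as_count_frame(X)
        self.snr_ = snr(X, self.panel, summary_method=self.summary,
                        threshold=self.threshold)
        self.kept_probes_ = filter_probes(self.snr_, self.panel)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "kept_probes_"):
            raise QcError("SnrProbeFilter is not fitted")
        X = _as_count_frame(X)
        keep = [p for p in self.kept_probes_ if p in X.columns]
        return X[keep]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.kept_probes_, dtype=object)


def _as_count_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise QcError("expected a DataFrame of counts indexed by roi_id")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise QcError("counts contain non-finite values")
    if (X.to_numpy(dtype=float) < 0).any():
        raise QcError("counts contain negative values")
    return X
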