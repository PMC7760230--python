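"""Normalizer assessment and count normalization.

A good between-ROI normalizer should track per-ROI capture efficiency
(probe load, area, cellularity) while being unrelated to the underlying
biology. Candidate factors — individual housekeeper counts (GAPDH,
Histone H3, S6), their mean, the isotype-IgG mean, ROI area and nuclei
count — are assessed by pairwise Pearson correlation across ROIs; the
default normalization divides each ROI by the mean of its Histone H3 and
S6 counts, rescaled so the grand geometric mean of the factors is
preserved (outputs stay on the raw-count scale).

Global scaling alternatives are provided for datasets with systematic
compartment shifts (e.g. depressed normal-adjacent tissue counts), where a
single housekeeper approach would inflate the depressed group: the trimmed
mean of M-values (TMM) and relative log expression (RLE) median-ratio
factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import ProbePanel

logger = logging.getLogger("dspforge")

NORMALIZATION_METHODS = ("hk_mean", "igg", "tmm", "rle")
DEFAULT_HK_PROBES = ("Histone H3", "S6")


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Normalized expression plus a record of how it was produced."""

    values: pd.DataFrame = field(repr=False)
    method: str = "hk_mean"
    factors: pd.Series = field(repr=False, default=None)
    log2: bool = False
    pseudo_count: float = 0.0


# ---------------------------------------------------------------------------
# correlation primitives

def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input (undefined r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise NormalizationError("pearson_r requires equal-length vectors")
    if x.size < 3:
        raise NormalizationError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NormalizationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def build_factor_table(counts: pd.DataFrame, panel: ProbePanel,
                       roi_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-ROI candidate normalization factors.

    Columns: each housekeeper's count, ``hk_mean`` (mean of Histone H3 and
    S6), ``igg_mean``, and ``area`` / ``nuclei`` when a ROI table is given.
    """
    out = pd.DataFrame(index=counts.index)
    for hk in panel.housekeepers:
        if hk in counts.columns:
            out[hk] = counts[hk]
    hk_pair = [p for p in DEFAULT_HK_PROBES if p in counts.columns]
    if len(hk_pair) == len(DEFAULT_HK_PROBES):
        out["hk_mean"] = counts[list(hk_pair)].mean(axis=1)
    else:
        missing = sorted(set(DEFAULT_HK_PROBES) - set(hk_pair))
        logger.warning("hk_mean unavailable; missing housekeeper(s): %s", missing)
    igg = [p for p in panel.igg_controls if p in counts.columns]
    if igg:
        out["igg_mean"] = counts[igg].mean(axis=1)
    if roi_table is not None:
        meta = roi_table.set_index("roi_id").reindex(counts.index)
        for col in ("area", "nuclei"):
            if col in meta.columns and meta[col].notna().any():
                out[col] = pd.to_numeric(meta[col])
    return out


@dataclass
class NormalizerAssessment:
    """Pairwise Pearson matrix over candidate factors and a recommendation."""

    correlations: pd.DataFrame = field(repr=False)
    n: pd.DataFrame = field(repr=False)
    recommended: str = "hk_mean"
    excluded: list[str] = field(default_factory=list)


def assess_normalizers(factors: pd.DataFrame) -> NormalizerAssessment:
    """All pairwise correlations between candidate factors.

    The recommendation is advisory: the housekeeper-derived factor with the
    highest minimum correlation to the non-biological references (IgG mean,
    area, nuclei). Constant factors (e.g. every ROI at maximum geometry)
    are excluded with a warning.
    """
    cols = list(factors.columns)
    complete = factors.dropna()
    if len(complete) < 3:
        raise NormalizationError("assessment requires >=3 ROIs with complete factors")
    excluded = [c for c in cols if np.ptp(complete[c].to_numpy(dtype=float)) == 0]
    for c in excluded:
        logger.warning("factor %r is constant across ROIs; "
                       "excluded from recommendation", c)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    n = pd.DataFrame(len(complete), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = factors[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if a in excluded or b in excluded or len(pair) < 3:
                val = np.nan
            else:
                val = pearson_r(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = val
    hk_candidates = [c for c in cols
                     if c not in excluded and (c == "hk_mean" or c in
                        ("GAPDH", "Histone H3", "S6"))]
    references = [c for c in ("igg_mean", "area", "nuclei")
                  if c in cols and c not in excluded]
    recommended = "hk_mean" if "hk_mean" in hk_candidates else (
        hk_candidates[0] if hk_candidates else cols[0])
    if hk_candidates and references:
        worst = {c: np.nanmin([r.loc[c, ref] for ref in references])
                 for c in hk_candidates}
        recommended = max(worst, key=worst.get)
    return NormalizerAssessment(correlations=r, n=n, recommended=recommended,
                                excluded=excluded)


# ---------------------------------------------------------------------------
# housekeeper normalization

def _gmean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


class HousekeeperNormalizer(BaseEstimator, TransformerMixin):
    """Divide each ROI by its housekeeper factor, anchored to the grand
    geometric mean of the factors so outputs stay count-scaled.

    Parameters
    ----------
    panel : ProbePanel
    probes : sequence of str, default ("Histone H3", "S6")
        Housekeeper probes entering the per-ROI factor.
    mean : {"arithmetic", "geometric"}, default "arithmetic"
        How the named housekeeper counts are combined.
    log2, pseudo_count : optional log2 output.

    Attributes
    ----------
    factors_ : pandas.Series — per-ROI factor from the fitted matrix.
    anchor_ : float — grand geometric mean of the fitted factors.
    """

    def __init__(self, panel: ProbePanel, probes: Sequence[str] = DEFAULT_HK_PROBES,
                 mean: str = "arithmetic", log2: bool = False,
                 pseudo_count: float = 1.0):
        self.panel = panel
        self.probes = probes
        self.mean = mean
        self.log2 = log2
        self.pseudo_count = pseudo_count

    def _factors(self, X: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.probes if p not in X.columns]
        if missing:
            raise NormalizationError(f"housekeeper probe(s) absent: {missing}")
        sub = X[list(self.probes)].to_numpy(dtype=float)
        if self.mean == "arithmetic":
            f = sub.mean(axis=1)
        elif self.mean == "geometric":
            with np.errstate(divide="ignore"):
                f = np.exp(np.log(sub).mean(axis=1))
        else:
            raise NormalizationError("mean must be 'arithmetic' or 'geometric'")
        factors = pd.Series(f, index=X.index, name="hk_factor")
        bad = ~(factors > 0) | ~np.isfinite(factors)
        if bad.any():
            logger.warning("non-positive housekeeper factor; ROI(s) excluded: %s",
                           factors.index[bad].tolist())
            factors = factors[~bad]
        if factors.empty:
            raise NormalizationError("no ROI has a positive housekeeper factor")
        return factors

    def fit(self, X: pd.DataFrame, y=None) -> "HousekeeperNormalizer":
        factors = self._factors(X)
        self.factors_ = factors
        self.anchor_ = _gmean(factors.to_numpy())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "anchor_"):
            raise NormalizationError("normalizer is not fitted")
        factors = self._factors(X)
        scaled = X.loc[factors.index].mul(self.anchor_ / factors, axis=0)
        if self.log2:
            scaled = _log2_frame(scaled, self.pseudo_count)
        return scaled

    def to_normalized_matrix(self, X: pd.DataFrame) -> NormalizedMatrix:
        values = self.fit(X).transform(X)
        return NormalizedMatrix(values=values, method="hk_mean",
                                factors=self.factors_ / self.anchor_,
                                log2=self.log2,
                                pseudo_count=self.pseudo_count if self.log2 else 0.0)


def normalize_hk(counts: pd.DataFrame, panel: ProbePanel,
                 probes: Sequence[str] = DEFAULT_HK_PROBES,
                 mean: str = "arithmetic") -> NormalizedMatrix:
    """Housekeeper-mean normalization (Histone H3 / S6 by default)."""
    return HousekeeperNormalizer(panel, probes=probes, mean=mean).to_normalized_matrix(counts)


def normalize_igg(counts: pd.DataFrame, panel: ProbePanel) -> NormalizedMatrix:
    """IgG-mean normalization: the same scheme keyed on the isotype controls."""
    nm = HousekeeperNormalizer(panel, probes=tuple(panel.igg_controls)
                               ).to_normalized_matrix(counts)
    return replace(nm, method="igg")


# ---------------------------------------------------------------------------
# global scaling (TMM / RLE)

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
                     lib_ref: float, logratio_trim: float,
                     sum_trim: float) -> float:
    """TMM factor of one ROI against the reference: doubly trimmed weighted
    mean of M-values (trim ``logratio_trim`` from each tail of M and
    ``sum_trim`` from each tail of A), precision weights from the delta
    method on binomial counts."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    f = 2.0 ** (np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))
    return float(f) if np.isfinite(f) and f > 0 else 1.0


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.30,
                sum_trim: float = 0.05) -> pd.Series:
    """Per-ROI TMM scaling factors, normalized to multiply to 1.

    The factor combines the library size with the trimmed-mean correction
    against the reference ROI (the ROI whose upper-quartile fraction is
    closest to the mean upper quartile).
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise NormalizationError("TMM requires >=2 ROIs")
    nonzero = X.sum(axis=0) > 0
    if (~nonzero).any():
        logger.warning("dropping %d all-zero probe(s) from TMM factor computation",
                       int((~nonzero).sum()))
        X = X[:, nonzero]
    lib = X.sum(axis=1)
    uq = np.array([np.quantile(row / l, 0.75) for row, l in zip(X, lib)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([
        _tmm_pair_factor(X[i], X[ref_idx], lib[i], lib[ref_idx],
                         logratio_trim, sum_trim)
        for i in range(X.shape[0])
    ])
    scale = lib * f
    scale = scale / np.exp(np.mean(np.log(scale)))
    return pd.Series(scale, index=counts.index, name="tmm_factor")


def rle_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-ratio (relative log expression) factors, product 1."""
    X = counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise NormalizationError("RLE requires >=2 ROIs")
    with np.errstate(divide="ignore"):
        log_x = np.log(X)
    finite = np.isfinite(log_x).all(axis=0)
    if not finite.any():
        raise NormalizationError("RLE reference undefined: every probe has a zero")
    if (~finite).any():
        logger.warning("dropping %d probe(s) with zeros from RLE reference",
                       int((~finite).sum()))
    log_ref = log_x[:, finite].mean(axis=0)
    s = np.exp(np.median(log_x[:, finite] - log_ref, axis=1))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.index, name="rle_factor")


class GlobalScalingNormalizer(BaseEstimator, TransformerMixin):
    """TMM or RLE global scaling: divide each ROI by its scaling factor.

    Attributes
    ----------
    factors_ : pandas.Series — per-ROI factors (product 1).
    """

    def __init__(self, method: str = "tmm", logratio_trim: float = 0.30,
                 sum_trim: float = 0.05):
        self.method = method
        self.logratio_trim = logratio_trim
        self.sum_trim = sum_trim

    def fit(self, X: pd.DataFrame, y=None) -> "GlobalScalingNormalizer":
        if self.method == "tmm":
            self.factors_ = tmm_factors(X, self.logratio_trim, self.sum_trim)
        elif self.method == "rle":
            self.factors_ = rle_factors(X)
        else:
            raise NormalizationError(
                f"unknown global scaling method {self.method!r}; use 'tmm' or 'rle'")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "factors_"):
            raise NormalizationError("normalizer is not fitted")
        return X.loc[self.factors_.index].div(self.factors_, axis=0)


def normalize_global(counts: pd.DataFrame, method: str = "tmm") -> NormalizedMatrix:
    est = GlobalScalingNormalizer(method=method)
    values = est.fit(counts).transform(counts)
    return NormalizedMatrix(values=values, method=method, factors=est.factors_)


# ---------------------------------------------------------------------------
# log2

def _log2_frame(values: pd.DataFrame, pseudo_count: float) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise NormalizationError("log2 transform requires nonnegative values")
    return pd.DataFrame(np.log2(arr + pseudo_count), index=values.index,
                        columns=values.columns)


def log2_transform(norm: NormalizedMatrix | pd.DataFrame,
                   pseudo_count: float = 1.0) -> NormalizedMatrix:
    """log2(value + pseudo_count); records the flag and pseudo-count."""
    if isinstance(norm, pd.DataFrame):
        return NormalizedMatrix(values=_log2_frame(norm, pseudo_count),
                                method="raw", factors=None, log2=True,
                                pseudo_count=pseudo_count)
    if norm.log2:
        return norm
    return replace(norm, values=_log2_frame(norm.values, pseudo_count),
                   log2=True, pseudo_count=pseudo_count)


def normalize_within_groups(counts: pd.DataFrame, panel: ProbePanel,
                            groups: pd.Series, method: str = "hk_mean",
                            **kwargs) -> NormalizedMatrix:
    """Normalize each ROI group (typically a tissue compartment) separately.

    A single global factor rule inflates a group whose counts are
    systematically lower (the depressed normal-adjacent-tissue case);
    per-group normalization sidesteps that at the cost of removing
    genuine between-group level differences. Factors within each group are
    anchored to that group's own geometric mean.
    """
    groups = groups.reindex(counts.index)
    if groups.isna().any():
        raise NormalizationError("every ROI needs a group label")
    parts = []
    factor_parts = []
    for _, idx in counts.groupby(groups, sort=True).groups.items():
        nm = normalize_counts(counts.loc[idx], panel, method=method, **kwargs)
        parts.append(nm.values)
        factor_parts.append(nm.factors)
    values = pd.concat(parts).reindex(counts.index).dropna(how="all")
    factors = pd.concat(factor_parts).reindex(values.index)
    return NormalizedMatrix(values=values, method=f"{method}:within_group",
                            factors=factors)


def normalize_counts(counts: pd.DataFrame, panel: ProbePanel,
                     method: str = "hk_mean", **kwargs) -> NormalizedMatrix:
    """Dispatch on normalization method name."""
    if method == "hk_mean":
        return normalize_hk(counts, panel, **kwargs)
    if method == "igg":
        return normalize_igg(counts, panel)
    if method in ("tmm", "rle"):
        return normalize_global(counts, method=method)
    raise NormalizationError(
        f"unknown normalization method {method!r}; allowed: {list(NORMALIZATION_METHODS)}")
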