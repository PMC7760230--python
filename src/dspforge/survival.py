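"""Univariate Cox proportional-hazards screening of probe expression.

Each probe's per-patient log2 expression (mean over that patient's ROIs of
the compartment) is fit against overall survival in an unadjusted,
single-covariate Cox model. The partial likelihood uses Efron's handling
of tied event times and is maximized by Newton-Raphson with the analytic
gradient and Hessian; the variance comes from the inverse observed
information. Results are ranked by hazard ratio; HR < 1 indicates
association with longer survival. No multiplicity adjustment is applied by
default (the screen is explicitly exploratory); a BH column is optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .diffexp import bh_adjust
from .normalize import NormalizedMatrix, log2_transform

logger = logging.getLogger("dspforge")

MAX_ABS_BETA = 20.0
SCORE_TOL = 1e-9
MAX_ITER = 50


class CoxError(ValueError):
    pass


@dataclass
class CoxResult:
    probe_id: str | None
    compartment: str | None
    n: int
    n_events: int
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool


def _efron_derivatives(beta: float, x: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> tuple[float, float, float]:
    """Log partial likelihood, score and observed information (Efron ties)."""
    order = np.argsort(-time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    eta = beta * x
    # guard against overflow for extreme beta during step-halving
    w = np.exp(np.clip(eta, -500, 500))
    wx = w * x
    wxx = wx * x
    ll = 0.0
    score = 0.0
    info = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = x.size
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            s0 += w[j]
            s1 += wx[j]
            s2 += wxx[j]
            j += 1
        dead = [k for k in range(i, j) if event[k]]
        d = len(dead)
        if d:
            d0 = sum(w[k] for k in dead)
            d1 = sum(wx[k] for k in dead)
            d2 = sum(wxx[k] for k in dead)
            ll += sum(eta[k] for k in dead)
            score += sum(x[k] for k in dead)
            for l in range(d):
                f = l / d
                phi0 = s0 - f * d0
                phi1 = s1 - f * d1
                phi2 = s2 - f * d2
                ll -= np.log(phi0)
                score -= phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
        i = j
    return ll, score, info


def cox_score_test(x, time, event) -> float:
    """Score (Rao) chi-square at beta = 0; equals the log-rank statistic
    for a binary covariate without tied event times."""
    x = np.asarray(x, dtype=float)
    _, u, i0 = _efron_derivatives(0.0, x, np.asarray(time, dtype=float),
                                  np.asarray(event, dtype=bool))
    if i0 <= 0:
        raise CoxError("score test undefined: zero information")
    return float(u * u / i0)


def cox_fit(x, surv: pd.DataFrame | None = None, *, time=None, event=None,
            probe_id: str | None = None,
            compartment: str | None = None) -> CoxResult:
    """Fit a single-covariate Cox model.

    ``x`` may be a Series indexed by patient_id (aligned against ``surv``)
    or an array aligned with ``time`` / ``event``.
    """
    if surv is not None:
        s = surv.set_index("patient_id") if "patient_id" in surv.columns else surv
        if isinstance(x, pd.Series):
            common = [p for p in x.index if p in s.index]
            x_arr = x.loc[common].to_numpy(dtype=float)
            time_arr = s.loc[common, "time"].to_numpy(dtype=float)
            event_arr = s.loc[common, "event"].to_numpy(dtype=bool)
        else:
            x_arr = np.asarray(x, dtype=float)
            time_arr = s["time"].to_numpy(dtype=float)
            event_arr = s["event"].to_numpy(dtype=bool)
    else:
        x_arr = np.asarray(x, dtype=float)
        time_arr = np.asarray(time, dtype=float)
        event_arr = np.asarray(event, dtype=bool)
    if not (x_arr.size == time_arr.size == event_arr.size):
        raise CoxError("covariate and survival records are misaligned")
    keep = np.isfinite(x_arr)
    x_arr, time_arr, event_arr = x_arr[keep], time_arr[keep], event_arr[keep]
    n = x_arr.size
    n_events = int(event_arr.sum())
    if n_events < 2:
        raise CoxError(f"need >=2 events, got {n_events}")
    if np.ptp(x_arr) == 0:
        raise CoxError("constant covariate")

    beta = 0.0
    ll, score, info = _efron_derivatives(beta, x_arr, time_arr, event_arr)
    converged = False
    for _ in range(MAX_ITER):
        if abs(score) < SCORE_TOL:
            converged = True
            break
        if info <= 0:
            break
        step = score / info
        # step-halving to keep the partial likelihood nondecreasing
        new_beta = beta + step
        new_ll, new_score, new_info = _efron_derivatives(
            new_beta, x_arr, time_arr, event_arr)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _efron_derivatives(
                new_beta, x_arr, time_arr, event_arr)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > MAX_ABS_BETA:
            break
    else:
        converged = abs(score) < SCORE_TOL
    if abs(score) < SCORE_TOL and abs(beta) <= MAX_ABS_BETA:
        converged = True
    if abs(beta) > MAX_ABS_BETA:
        logger.warning("monotone likelihood: |beta| > %s; flagged non-converged",
                       MAX_ABS_BETA)
        converged = False

    se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    with np.errstate(over="ignore"):  # divergent fits may overflow the CI
        hr = float(np.exp(beta))
        ci_low = float(np.exp(beta - 1.959963984540054 * se))
        ci_high = float(np.exp(beta + 1.959963984540054 * se))
    return CoxResult(
        probe_id=probe_id, compartment=compartment, n=n, n_events=n_events,
        beta=float(beta), se=float(se), hr=hr, ci_low=ci_low, ci_high=ci_high,
        p=float(p), converged=converged,
    )


# ---------------------------------------------------------------------------
# per-compartment screen

def patient_expression(norm, roi_table: pd.DataFrame, compartment: str,
                       use_log2: bool = True) -> pd.DataFrame:
    """Per-patient mean (log2) expression over the compartment's ROIs."""
    if isinstance(norm, NormalizedMatrix):
        values = (norm.values if norm.log2 or not use_log2
                  else log2_transform(norm).values)
    else:
        values = log2_transform(norm).values if use_log2 else norm
    meta = roi_table.set_index("roi_id").reindex(values.index)
    mask = (meta["compartment"] == compartment) & meta["patient_id"].notna()
    sub = values.loc[mask.to_numpy()]
    pts = meta.loc[mask.to_numpy(), "patient_id"].to_numpy()
    return sub.groupby(pts).mean().rename_axis("patient_id")


def screen_compartment(norm, roi_table: pd.DataFrame, surv: pd.DataFrame,
                       compartment: str, probes=None,
                       dichotomize: bool = False,
                       adjust: bool = False) -> pd.DataFrame:
    """Univariate Cox screen of every probe within one compartment.

    Returns a forest-plot-ready table ranked by hazard ratio (protective
    first). Probes with <2 events or constant covariates are skipped with
    a warning. ``dichotomize`` replaces the continuous log2 covariate with
    a median-split indicator.
    """
    expr = patient_expression(norm, roi_table, compartment)
    if expr.empty:
        logger.warning("compartment %r has no patient-linked ROIs", compartment)
        return _empty_screen()
    if probes is not None:
        expr = expr[[p for p in probes if p in expr.columns]]
    rows = []
    for probe in expr.columns:
        xv = expr[probe]
        if dichotomize:
            xv = (xv > xv.median()).astype(float)
        try:
            res = cox_fit(xv, surv, probe_id=probe, compartment=compartment)
        except CoxError as exc:
            logger.warning("probe %s skipped in %s screen: %s",
                           probe, compartment, exc)
            continue
        rows.append(res)
    if not rows:
        return _empty_screen()
    out = pd.DataFrame([vars(r) for r in rows])
    out = out.sort_values("hr", kind="stable").reset_index(drop=True)
    if adjust:
        out["p_adj"] = bh_adjust(out["p"])
    return out


def _empty_screen() -> pd.DataFrame:
    return pd.DataFrame(columns=["probe_id", "compartment", "n", "n_events",
                                 "beta", "se", "hr", "ci_low", "ci_high",
                                 "p", "converged"])


class CoxScreen(BaseEstimator):
    """Estimator wrapper: fit(X, y) where X is a patient x probe log2
    expression frame and y a survival table (patient_id, time, event).

    Attributes
    ----------
    results_ : pandas.DataFrame ranked by hazard ratio.
    """

    def __init__(self, dichotomize: bool = False, adjust: bool = False):
        self.dichotomize = dichotomize
        self.adjust = adjust

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "CoxScreen":
        rows = []
        for probe in X.columns:
            xv = X[probe]
            if self.dichotomize:
                xv = (xv > xv.median()).astype(float)
            try:
                rows.append(cox_fit(xv, y, probe_id=probe))
            except CoxError as exc:
                logger.warning("probe %s skipped: %s", probe, exc)
        self.results_ = (pd.DataFrame([vars(r) for r in rows])
                         .sort_values("hr", kind="stable")
                         .reset_index(drop=True)
                         if rows else _empty_screen())
        if self.adjust and len(self.results_):
            self.results_["p_adj"] = bh_adjust(self.results_["p"])
        return self
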