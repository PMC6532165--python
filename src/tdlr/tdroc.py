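"""Time-dependent ROC curves, AUC(t), the smoothed ROC derivative, and cutoffs.

The cumulative/dynamic convention is used throughout: at time t, cases are
subjects with T <= t and controls those with T > t.  Censoring is handled with
conditional Kaplan-Meier weighting: for each threshold c,

    P(X > c, T > t) = S_KM(t | X > c) * P(X > c)

so TPR(c, t) = [P(X > c) - P(X > c, T > t)] / (1 - S(t)) and
FPR(c, t) = P(X > c, T > t) / S(t).  With no censoring this reduces exactly to
the empirical ROC of the marker against the indicator of T <= t.

The derivative of the ROC with respect to the false positive rate equals the
likelihood ratio of the marker densities among cases vs controls; evaluated at
an FPR equal to the placement value of x, it coincides with TD-LR(x, t), which
also motivates picking an "optimal" dichotomization cutoff where TD-LR is
approximately 1 across time points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .surface import TDLRSurface
from .survival_core import SurvivalDataset

__all__ = ["TDROCCurve", "CutoffResult", "td_roc", "td_auc_profile",
           "roc_derivative", "optimal_cutoff"]


@dataclass(frozen=True)
class TDROCCurve:
    """TD-ROC at a fixed time: FPR grid, TPR values, trapezoidal AUC."""

    t: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    derivative: Optional[np.ndarray] = None
    bandwidth: Optional[float] = None


def _km_at(times_sorted: np.ndarray, events_sorted: np.ndarray, t: float) -> float:
    """Product-limit survival at t for a time-sorted subset (grouped over ties)."""
    k = np.searchsorted(times_sorted, t, side="right")
    ev = times_sorted[:k][events_sorted[:k] == 1]
    if len(ev) == 0:
        return 1.0
    uniq, d = np.unique(ev, return_counts=True)
    r = len(times_sorted) - np.searchsorted(times_sorted, uniq, side="left")
    return float(np.prod(1.0 - d / r))


def td_roc(data: SurvivalDataset, t: float) -> TDROCCurve:
    """Cumulative/dynamic TD-ROC at time t with KM censoring adjustment.

    Requires t inside the span of observed times, with both the case
    (T <= t) and control (T > t) probabilities estimable (marginal KM
    strictly inside (0, 1)).
    """
    ev_times = data.time[data.event == 1]
    if len(ev_times) == 0:
        raise ValueError("TD-ROC requires at least one event")
    if t < ev_times.min() or t > data.time.max():
        raise ValueError(
            f"t={t} outside the estimable span [{ev_times.min()}, {data.time.max()}]")
    n = len(data)
    # subjects sorted by marker descending; prefixes are the X > c subsets
    by_marker = np.argsort(-data.marker, kind="stable")
    xm = data.marker[by_marker]
    by_time = np.argsort(data.time, kind="stable")
    s_marg = _km_at(data.time[by_time], data.event[by_time], t)
    if not (0.0 < s_marg < 1.0):
        raise ValueError(f"marginal survival at t={t} is {s_marg}; ROC undefined")
    # prefix boundaries at each change of marker value (thresholds = unique values)
    change = np.flatnonzero(np.diff(xm) != 0) + 1
    prefix_sizes = np.concatenate(([0], change, [n]))
    fpr = np.empty(len(prefix_sizes))
    tpr = np.empty(len(prefix_sizes))
    for j, k in enumerate(prefix_sizes):
        if k == 0:
            fpr[j] = tpr[j] = 0.0
            continue
        idx = by_marker[:k]
        order = np.argsort(data.time[idx], kind="stable")
        s_sub = _km_at(data.time[idx][order], data.event[idx][order], t)
        p = k / n
        joint = s_sub * p                       # P(X > c, T > t)
        fpr[j] = joint / s_marg
        tpr[j] = (p - joint) / (1.0 - s_marg)
    # threshold (prefix) order is the natural curve order: both coordinates are
    # nondecreasing exactly when there is no censoring, and the KM adjustment
    # can only produce small local violations, ironed out monotonically here
    fpr = np.maximum.accumulate(np.clip(fpr, 0.0, 1.0))
    tpr = np.maximum.accumulate(np.clip(tpr, 0.0, 1.0))
    auc = float(np.trapezoid(tpr, fpr))
    return TDROCCurve(t=float(t), fpr=fpr, tpr=tpr, auc=auc)


def td_auc_profile(data: SurvivalDataset, t_grid: Sequence[float]) -> pd.DataFrame:
    """AUC(t) for each t in the grid; per-t failures recorded as NaN rows."""
    rows = []
    for t in np.asarray(t_grid, dtype=float):
        try:
            rows.append((t, td_roc(data, t).auc))
        except ValueError as exc:
            import warnings
            warnings.warn(f"AUC at t={t} not estimable: {exc}", RuntimeWarning,
                          stacklevel=2)
            rows.append((t, np.nan))
    return pd.DataFrame(rows, columns=["t", "auc"])


def roc_derivative(curve: TDROCCurve, bandwidth: float = 0.1) -> TDROCCurve:
    """Local-linear smoothed derivative of TPR with respect to FPR.

    A Gaussian kernel of the given bandwidth (FPR units) weights a local
    linear fit at each support point; the fitted slope is the derivative,
    floored at 0.  Requires at least 10 support points.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(curve.fpr) < 10:
        raise ValueError("ROC derivative needs at least 10 support points")
    f, y = curve.fpr, curve.tpr
    deriv = np.empty(len(f))
    for i, f0 in enumerate(f):
        w = np.exp(-0.5 * ((f - f0) / bandwidth) ** 2)
        sw = w.sum()
        fbar = (w * f).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (f - fbar) ** 2).sum()
        deriv[i] = (w * (f - fbar) * (y - ybar)).sum() / sxx if sxx > 0 else 0.0
    deriv = np.maximum(deriv, 0.0)
    return replace(curve, derivative=deriv, bandwidth=float(bandwidth))


@dataclass(frozen=True)
class CutoffResult:
    """Summary cutoff (median of per-t roots of log TD-LR = 0) and per-t roots."""

    cutoff: float
    per_t: pd.Series
    indeterminate: bool = False


def optimal_cutoff(surface: TDLRSurface, t_subset: Optional[Sequence[float]] = None,
                   ) -> CutoffResult:
    """Marker value where log TD-LR crosses 0 (TD-LR ~ 1), per time and overall.

    For each t, the root along x is found by linear interpolation between the
    grid cells bracketing the sign change; times without a crossing are NaN.
    A row identically 0 makes every x a root; the mid-grid value is reported
    with the ``indeterminate`` flag set.
    """
    if t_subset is None:
        t_subset = surface.t_grid
    t_subset = np.asarray(t_subset, dtype=float)
    x = surface.x_grid
    roots, any_indet = {}, False
    for t in t_subset:
        i = int(np.argmin(np.abs(surface.t_grid - t)))
        v = surface.log_tdlr[i]
        ok = np.isfinite(v)
        xv, vv = x[ok], v[ok]
        if len(vv) < 2:
            roots[t] = np.nan
            continue
        if np.all(np.abs(vv) < 1e-12):
            roots[t] = float(0.5 * (xv[0] + xv[-1]))
            any_indet = True
            continue
        sign_change = np.flatnonzero(np.diff(np.signbit(vv)))
        exact = np.flatnonzero(vv == 0.0)
        if len(exact):
            roots[t] = float(xv[exact[0]])
        elif len(sign_change):
            j = sign_change[0]
            roots[t] = float(xv[j] - vv[j] * (xv[j + 1] - xv[j]) / (vv[j + 1] - vv[j]))
        else:
            roots[t] = np.nan
    per_t = pd.Series(roots, name="cutoff").sort_index()
    defined = per_t.dropna()
    if defined.empty:
        raise ValueError("log TD-LR does not cross 0 at any requested time")
    return CutoffResult(cutoff=float(defined.median()), per_t=per_t,
                        indeterminate=any_indet)
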