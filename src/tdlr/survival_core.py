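"""Survival estimation primitives for right-censored data with one continuous marker.

This module provides the two survival estimators the time-dependent likelihood
ratio is built from: the Kaplan-Meier product-limit estimator of the marginal
survival function S(t), and a univariate Cox proportional-hazards fit giving the
conditional survival function S(t | X = x) = S0(t)^exp(beta * x).

Conventions
-----------
* A subject is at risk at time s iff its observed time Z >= s; events at
  exactly s are in the risk set at s.
* Step functions are right-continuous: the value at an event time includes
  that event.
* The marker is centered at its sample mean before fitting; the baseline
  survival curve refers to the centered origin and :func:`conditional_survival`
  un-centers transparently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SurvivalDataset",
    "StepFunction",
    "StepSurvivalCurve",
    "CoxModel",
    "PHDiagnostic",
    "ConvergenceError",
    "km_estimate",
    "survival_at",
    "cox_fit",
    "log_partial_likelihood",
    "baseline_survival",
    "conditional_survival",
    "ph_diagnostic",
]


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration fails to converge."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-subject observed time Z = min(T, C), event flag delta, and marker X.

    The counting-process view D(t) = 1{Z <= t and event == 1} is derived from
    these fields; the latent failure and censoring times are never stored.
    """

    time: np.ndarray
    event: np.ndarray
    marker: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        marker = np.asarray(self.marker, dtype=float)
        if not (time.ndim == event.ndim == marker.ndim == 1):
            raise ValueError("time, event and marker must be one-dimensional")
        if not (len(time) == len(event) == len(marker)):
            raise ValueError("time, event and marker must have equal length")
        if len(time) == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all observed times must be finite and > 0")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicator must be coded 0/1")
        if not np.all(np.isfinite(marker)):
            raise ValueError("marker values must be finite")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))
        object.__setattr__(self, "marker", marker)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - self.event.mean()

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        mask = np.asarray(mask)
        return SurvivalDataset(self.time[mask], self.event[mask], self.marker[mask])

    def with_marker(self, marker: np.ndarray) -> "SurvivalDataset":
        """Same subjects with the marker replaced (e.g. by a transformed scale)."""
        return SurvivalDataset(self.time, self.event, marker)

    @classmethod
    def from_frame(cls, df, time: str = "time", event: str = "event",
                   marker: str = "marker") -> "SurvivalDataset":
        return cls(df[time].to_numpy(), df[event].to_numpy(), df[marker].to_numpy())


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with a starting value before the first jump."""

    jump_times: np.ndarray
    values: np.ndarray
    initial: float = 0.0

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if len(jt) != len(vals):
            raise ValueError("jump_times and values must have equal length")
        if len(jt) and np.any(np.diff(jt) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "values", vals)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("step functions are defined for t >= 0 only")
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        out = np.where(idx < 0, self.initial, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class StepSurvivalCurve:
    """Right-continuous step estimate of a survival function (KM or baseline S0).

    S(0) = 1 implicitly: the value before the first jump is 1.
    """

    jump_times: np.ndarray
    surv_probs: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        sp = np.asarray(self.surv_probs, dtype=float)
        nr = np.asarray(self.n_at_risk, dtype=int)
        if not (len(jt) == len(sp) == len(nr)):
            raise ValueError("curve fields must have equal length")
        if len(jt) == 0:
            raise ValueError("a survival curve needs at least one jump")
        if np.any(jt <= 0) or np.any(np.diff(jt) <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        if np.any(sp < 0) or np.any(sp > 1) or np.any(np.diff(sp) > 1e-12):
            raise ValueError("surv_probs must lie in [0,1] and be non-increasing")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "surv_probs", sp)
        object.__setattr__(self, "n_at_risk", nr)

    def __call__(self, t):
        return survival_at(self, t)


def survival_at(curve: StepSurvivalCurve, t):
    """Evaluate a step survival curve at ``t`` (scalar or array), right-continuously.

    Values before the first jump are 1; values after the last jump stay at the
    last estimate.  Negative ``t`` raises.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival functions are defined for t >= 0 only")
    idx = np.searchsorted(curve.jump_times, t, side="right") - 1
    out = np.where(idx < 0, 1.0, curve.surv_probs[np.clip(idx, 0, None)])
    return out if out.ndim else float(out)


def _risk_and_event_counts(data: SurvivalDataset):
    """Distinct event times with event counts d and risk-set sizes r."""
    order = np.argsort(data.time, kind="stable")
    times = data.time[order]
    events = data.event[order]
    ev_times = times[events == 1]
    uniq, counts = np.unique(ev_times, return_counts=True)
    # risk set at s: subjects with Z >= s
    at_risk = len(times) - np.searchsorted(times, uniq, side="left")
    return uniq, counts, at_risk


def km_estimate(data: SurvivalDataset) -> StepSurvivalCurve:
    """Kaplan-Meier product-limit estimate over the observed failure times.

    S_hat(t) = prod_{s in event times, s <= t} (1 - d_s / r_s) with r_s the
    number of subjects at risk (Z >= s).
    """
    if data.n_events == 0:
        raise ValueError("Kaplan-Meier estimation requires at least one event; "
                         "all subjects are censored")
    uniq, d, r = _risk_and_event_counts(data)
    surv = np.cumprod(1.0 - d / r)
    return StepSurvivalCurve(uniq, surv, r)


# ---------------------------------------------------------------------------
# Cox partial likelihood (univariate), Newton-Raphson with step-halving
# ---------------------------------------------------------------------------


class _CoxPrep:
    """Sorted arrays and tie-group bookkeeping reused across likelihood evaluations."""

    def __init__(self, data: SurvivalDataset, center: float, ties: str):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie-handling method {ties!r}")
        order = np.argsort(data.time, kind="stable")
        self.z = data.time[order]
        self.d = data.event[order].astype(bool)
        self.x = data.marker[order] - center
        ev_times = self.z[self.d]
        self.xe = self.x[self.d]                     # event-subject covariates, by time
        uniq, idx, counts = np.unique(ev_times, return_index=True, return_counts=True)
        self.group_start_in_events = idx             # reduceat boundaries over event arrays
        self.counts = counts
        self.risk_start = np.searchsorted(self.z, uniq, side="left")
        # Efron expansion: for group g with d_g tied events, terms l/d_g, l=0..d_g-1
        self.grp_idx = np.repeat(np.arange(len(uniq)), counts)
        offs = np.concatenate(([0], np.cumsum(counts)))[:-1]
        if ties == "efron":
            self.l_frac = (np.arange(len(self.grp_idx)) - offs[self.grp_idx]) / counts[self.grp_idx]
        else:
            self.l_frac = np.zeros(len(self.grp_idx))
        self.sum_xe = self.xe.sum()

    def loglik_grad_hess(self, beta: float):
        w = np.exp(beta * self.x)
        xw = self.x * w
        x2w = self.x * xw
        # suffix (risk-set) sums at each distinct event time
        rw = np.cumsum(w[::-1])[::-1]
        rxw = np.cumsum(xw[::-1])[::-1]
        rx2w = np.cumsum(x2w[::-1])[::-1]
        Rw = rw[self.risk_start]
        Rxw = rxw[self.risk_start]
        Rx2w = rx2w[self.risk_start]
        # tied-event sums per group
        we = np.exp(beta * self.xe)
        sw = np.add.reduceat(we, self.group_start_in_events)
        sxw = np.add.reduceat(self.xe * we, self.group_start_in_events)
        sx2w = np.add.reduceat(self.xe * self.xe * we, self.group_start_in_events)
        g = self.grp_idx
        denom = Rw[g] - self.l_frac * sw[g]
        a1 = Rxw[g] - self.l_frac * sxw[g]
        a2 = Rx2w[g] - self.l_frac * sx2w[g]
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            return -np.inf, np.nan, np.nan
        ll = beta * self.sum_xe - np.sum(np.log(denom))
        grad = self.sum_xe - np.sum(a1 / denom)
        hess = -np.sum(a2 / denom - (a1 / denom) ** 2)
        return ll, grad, hess


@dataclass
class CoxModel:
    """Univariate Cox proportional-hazards fit.

    ``baseline_curve`` is S0_hat at the centering value used during fitting
    (default: exp(-Lambda0_hat) with a Breslow cumulative hazard), so
    S(t | X = x) = S0_hat(t) ** exp(beta * (x - marker_center)).
    """

    beta: float
    se_beta: float
    log_partial_likelihood: float
    baseline_curve: StepSurvivalCurve
    baseline_cumhaz: StepFunction
    marker_center: float
    ties: str = "efron"
    n_iter: int = 0


def log_partial_likelihood(data: SurvivalDataset, beta: float, *,
                           center: Optional[float] = None,
                           ties: str = "efron") -> float:
    """Log partial likelihood at a given beta (marker centered at ``center``).

    Exposed so the fit can be checked against direct 1-D maximization.
    """
    if center is None:
        center = float(data.marker.mean())
    prep = _CoxPrep(data, center, ties)
    return prep.loglik_grad_hess(beta)[0]


def cox_fit(data: SurvivalDataset, *, ties: str = "efron",
            baseline: str = "breslow", max_iter: int = 100) -> CoxModel:
    """Maximize the univariate Cox partial likelihood by Newton-Raphson.

    Step-halving guards each update; convergence when |score| < 1e-9 or the
    relative change in log partial likelihood falls below 1e-12.
    """
    if data.n_events == 0:
        raise ValueError("Cox fit requires at least one event; all subjects censored")
    if np.ptp(data.marker) == 0:
        raise ValueError("marker is constant: the partial likelihood is flat in beta")
    center = float(data.marker.mean())
    prep = _CoxPrep(data, center, ties)
    beta = 0.0
    ll, grad, hess = prep.loglik_grad_hess(beta)
    for it in range(1, max_iter + 1):
        if abs(grad) < 1e-9:
            break
        step = grad / (-hess) if hess < 0 else np.sign(grad)
        new_beta, new = beta + step, None
        for _ in range(40):
            new = prep.loglik_grad_hess(new_beta)
            if np.isfinite(new[0]) and new[0] >= ll - 1e-14:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if new is None or not np.isfinite(new[0]):
            raise ConvergenceError(
                f"partial likelihood not improvable at iteration {it}; |score|={abs(grad):.3e}")
        rel_change = abs(new[0] - ll) / (abs(ll) + 1.0)
        beta, (ll, grad, hess) = new_beta, new
        if rel_change < 1e-12:
            break
        if abs(beta) > 500:
            raise ConvergenceError(
                f"beta diverging (|beta|>{500}); likely monotone likelihood; |score|={abs(grad):.3e}")
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations; last |score|={abs(grad):.3e}")
    if not (hess < 0):
        raise ConvergenceError("non-concave partial likelihood at optimum")
    se = float(np.sqrt(-1.0 / hess))
    model = CoxModel(beta=float(beta), se_beta=se, log_partial_likelihood=float(ll),
                     baseline_curve=None, baseline_cumhaz=None,  # type: ignore[arg-type]
                     marker_center=center, ties=ties, n_iter=it)
    model.baseline_cumhaz = _breslow_cumhaz(model, data)
    model.baseline_curve = baseline_survival(model, data, method=baseline)
    return model


def _breslow_cumhaz(model: CoxModel, data: SurvivalDataset) -> StepFunction:
    uniq, d, r = _risk_and_event_counts(data)
    order = np.argsort(data.time, kind="stable")
    z = data.time[order]
    w = np.exp(model.beta * (data.marker[order] - model.marker_center))
    rw = np.cumsum(w[::-1])[::-1]
    Rw = rw[np.searchsorted(z, uniq, side="left")]
    cumhaz = np.cumsum(d / Rw)
    return StepFunction(uniq, cumhaz, initial=0.0)


def baseline_survival(model: CoxModel, data: SurvivalDataset, *,
                      method: str = "breslow") -> StepSurvivalCurve:
    """Baseline survival S0_hat(t) at the centering value used in fitting.

    ``method='breslow'`` (default) sets S0 = exp(-Lambda0) with the Breslow
    cumulative hazard; ``method='kalbfleisch-prentice'`` solves the discrete
    product-form estimator, which reduces exactly to Kaplan-Meier when beta = 0
    and event times are distinct.
    """
    uniq, d, r = _risk_and_event_counts(data)
    order = np.argsort(data.time, kind="stable")
    z = data.time[order]
    ev = data.event[order].astype(bool)
    x = data.marker[order] - model.marker_center
    w = np.exp(model.beta * x)
    rw = np.cumsum(w[::-1])[::-1]
    starts = np.searchsorted(z, uniq, side="left")
    Rw = rw[starts]
    if method == "breslow":
        surv = np.exp(-np.cumsum(d / Rw))
    elif method == "kalbfleisch-prentice":
        factors = np.empty(len(uniq))
        for k, (s, Rk) in enumerate(zip(uniq, Rw)):
            wk = w[ev & (z == s)]
            if len(wk) == 1:
                ratio = wk[0] / Rk
                factors[k] = 0.0 if ratio >= 1.0 else (1.0 - ratio) ** (1.0 / wk[0])
            else:
                def f(alpha, wk=wk, Rk=Rk):
                    return np.sum(wk / (1.0 - alpha ** wk)) - Rk
                factors[k] = brentq(f, 1e-12, 1.0 - 1e-12)
        surv = np.cumprod(factors)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return StepSurvivalCurve(uniq, np.minimum.accumulate(np.clip(surv, 0.0, 1.0)), r)


def conditional_survival(model: CoxModel, t, x):
    """S_hat(t | X = x) = S0_hat(t) ** exp(beta * (x - center)).

    Accepts scalars or arrays in either argument (broadcast).
    """
    s0 = survival_at(model.baseline_curve, t)
    expo = np.exp(model.beta * (np.asarray(x, dtype=float) - model.marker_center))
    out = np.asarray(s0) ** expo
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PHDiagnostic:
    """Result of the proportional-hazards check (advisory only)."""

    statistic: float
    p_value: float
    time_transform: str


def ph_diagnostic(model: CoxModel, data: SurvivalDataset, *,
                  time_transform: str = "km") -> PHDiagnostic:
    """Grambsch-Therneau style test: scaled Schoenfeld residuals vs transformed time.

    Backed by lifelines' ``proportional_hazard_test`` on a refit of the same
    univariate model.  Advisory only; never blocks estimation.
    """
    if data.n_events < 5:
        raise ValueError("PH diagnostic requires at least 5 events")
    import pandas as pd
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = pd.DataFrame({"T": data.time, "E": data.event, "marker": data.marker})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    res = proportional_hazard_test(cph, df, time_transform=time_transform)
    stat = float(res.summary["test_statistic"].iloc[0])
    p = float(res.summary["p"].iloc[0])
    if not (np.isfinite(stat) and np.isfinite(p)):
        raise ValueError("PH diagnostic degenerate: residuals carry no variance")
    return PHDiagnostic(statistic=stat, p_value=p, time_transform=time_transform)
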