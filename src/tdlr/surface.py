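"""Time-dependent likelihood ratio (TD-LR) surfaces with bootstrap bands.

The TD-LR at marker value x and time t is the multiplicative update to the
marginal (prevalence-based) odds of failing at or before t obtained by
learning the marker value:

    TD-LR(x, t) = [(1 - S(t|x)) / S(t|x)] * [S(t) / (1 - S(t))]

estimated by plugging in the Cox conditional survival for S(t|x) and the
Kaplan-Meier estimate for S(t).  Values above 1 mean the marker value raises
the odds of an early event; below 1, lowers them; exactly 1, no update.

Cells where either survival estimate is exactly 0 or 1 have undefined odds and
are reported as NaN with a warning, never dropped or zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .survival_core import (
    CoxModel,
    StepSurvivalCurve,
    SurvivalDataset,
    conditional_survival,
    cox_fit,
    km_estimate,
    survival_at,
)

__all__ = ["TDLRSurface", "tdlr_point", "tdlr_fit", "tdlr_bootstrap",
           "default_t_grid", "default_x_grid"]

#: minimum fraction of effective bootstrap replicates that must yield a defined
#: value before a confidence band is reported for a cell
BOOT_DEFINED_FLOOR = 0.8


@dataclass
class TDLRSurface:
    """log TD-LR values on a (time x marker) lattice, with optional bands.

    Undefined cells are NaN.  Percentile bands may exclude the point estimate
    in skewed cases, but ``ci_lower <= ci_upper`` always holds where defined.
    """

    t_grid: np.ndarray
    x_grid: np.ndarray
    log_tdlr: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    level: float = 0.95
    n_boot: int = 0
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns t, x, log_tdlr, ci_lower, ci_upper."""
        tt, xx = np.meshgrid(self.t_grid, self.x_grid, indexing="ij")
        out = pd.DataFrame({
            "t": tt.ravel(),
            "x": xx.ravel(),
            "log_tdlr": self.log_tdlr.ravel(),
        })
        out["ci_lower"] = self.ci_lower.ravel() if self.ci_lower is not None else np.nan
        out["ci_upper"] = self.ci_upper.ravel() if self.ci_upper is not None else np.nan
        return out


def tdlr_point(km: StepSurvivalCurve, model: CoxModel, t: float, x: float) -> float:
    """Point estimate of TD-LR(x, t); NaN (with a warning) when odds degenerate.

    Degenerate cases are S_KM(t) in {0, 1} or S_Cox(t|x) in {0, 1}, where one
    of the odds is 0 or infinite.
    """
    if t <= 0:
        raise ValueError("TD-LR is defined for t > 0 only")
    s_marg = survival_at(km, t)
    s_cond = conditional_survival(model, t, x)
    if not (0.0 < s_marg < 1.0) or not (0.0 < s_cond < 1.0):
        warnings.warn(
            f"TD-LR undefined at (t={t!r}, x={x!r}): survival estimate on the boundary",
            RuntimeWarning, stacklevel=2)
        return float("nan")
    return ((1.0 - s_cond) / s_cond) * (s_marg / (1.0 - s_marg))


def default_t_grid(data: SurvivalDataset, n: int = 12) -> np.ndarray:
    """12 equally spaced times between the 5th and 95th percentile of event times."""
    ev = data.time[data.event == 1]
    lo, hi = np.percentile(ev, [5, 95])
    if lo == hi:
        return np.asarray([lo], dtype=float)
    return np.linspace(lo, hi, n)


def default_x_grid(data: SurvivalDataset, n: int = 21) -> np.ndarray:
    """21 equally spaced marker values between the 2.5th and 97.5th percentiles."""
    lo, hi = np.percentile(data.marker, [2.5, 97.5])
    if lo == hi:
        return np.asarray([lo], dtype=float)
    return np.linspace(lo, hi, n)


def _surface_values(km: StepSurvivalCurve, model: CoxModel,
                    t_grid: np.ndarray, x_grid: np.ndarray,
                    warn: bool = True) -> np.ndarray:
    """Vectorized log TD-LR on the grid; NaN at degenerate cells."""
    s_marg = survival_at(km, t_grid)                       # (T,)
    s0 = survival_at(model.baseline_curve, t_grid)         # (T,)
    expo = np.exp(model.beta * (x_grid - model.marker_center))  # (X,)
    s_cond = s0[:, None] ** expo[None, :]                  # (T, X)
    ok = ((s_marg > 0) & (s_marg < 1))[:, None] & ((s_cond > 0) & (s_cond < 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lr = (np.log1p(-s_cond) - np.log(s_cond)
                  + (np.log(s_marg) - np.log1p(-s_marg))[:, None])
    log_lr = np.where(ok, log_lr, np.nan)
    if warn and not ok.all():
        warnings.warn(
            f"{np.count_nonzero(~ok)} grid cell(s) undefined: survival estimate "
            "on the boundary", RuntimeWarning, stacklevel=2)
    return log_lr


def _validate_grids(data: SurvivalDataset, t_grid, x_grid):
    t_grid = np.sort(np.asarray(t_grid, dtype=float))
    x_grid = np.sort(np.asarray(x_grid, dtype=float))
    if len(t_grid) == 0 or len(x_grid) == 0:
        raise ValueError("grids must be non-empty")
    if np.any(t_grid <= 0):
        raise ValueError("t_grid values must be positive")
    if t_grid[-1] > data.time.max():
        raise ValueError("t_grid extends beyond the last observed time")
    return t_grid, x_grid


def tdlr_fit(data: SurvivalDataset, t_grid=None, x_grid=None, *,
             ties: str = "efron", baseline: str = "breslow") -> TDLRSurface:
    """Estimate the log TD-LR surface on a (time x marker) grid.

    One KM fit and one Cox fit are reused across all grid cells.  Default
    grids span the central mass of the observed event times and marker values.
    """
    if t_grid is None:
        t_grid = default_t_grid(data)
    if x_grid is None:
        x_grid = default_x_grid(data)
    km = km_estimate(data)
    model = cox_fit(data, ties=ties, baseline=baseline)
    t_grid, x_grid = _validate_grids(data, t_grid, x_grid)
    log_lr = _surface_values(km, model, t_grid, x_grid)
    return TDLRSurface(t_grid=t_grid, x_grid=x_grid, log_tdlr=log_lr)


def tdlr_bootstrap(data: SurvivalDataset, t_grid=None, x_grid=None, *,
                   n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                   ties: str = "efron", baseline: str = "breslow") -> TDLRSurface:
    """Pointwise bootstrap percentile bands for the log TD-LR surface.

    Subjects (time, event, marker triples) are resampled with replacement;
    KM and Cox are refit per replicate.  Replicates with zero events or a
    constant marker are discarded; ``n_boot`` on the result is the effective
    count.  A band is reported only where at least 80% of effective replicates
    yield a defined value.  Replicate r uses a deterministically derived
    substream of ``seed``, so results do not depend on execution order.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    point = tdlr_fit(data, t_grid, x_grid, ties=ties, baseline=baseline)
    t_grid, x_grid = point.t_grid, point.x_grid
    n = len(data)
    children = np.random.SeedSequence(seed).spawn(n_boot)
    reps = []
    n_discarded = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ss in children:
            rng = np.random.default_rng(ss)
            idx = rng.integers(0, n, n)
            boot = SurvivalDataset(data.time[idx], data.event[idx], data.marker[idx])
            if boot.n_events == 0 or np.ptp(boot.marker) == 0:
                n_discarded += 1
                continue
            try:
                km = km_estimate(boot)
                model = cox_fit(boot, ties=ties, baseline=baseline)
            except Exception:
                n_discarded += 1
                continue
            reps.append(_surface_values(km, model, t_grid, x_grid, warn=False))
    if n_discarded:
        warnings.warn(f"{n_discarded} degenerate bootstrap replicate(s) discarded",
                      RuntimeWarning, stacklevel=2)
    if not reps:
        raise ValueError("all bootstrap replicates were degenerate")
    stack = np.stack(reps)                                   # (B, T, X)
    n_eff = len(reps)
    defined = np.count_nonzero(np.isfinite(stack), axis=0)
    alpha = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(stack, 100 * alpha, axis=0)
        hi = np.nanpercentile(stack, 100 * (1 - alpha), axis=0)
    band_ok = defined >= BOOT_DEFINED_FLOOR * n_eff
    lo = np.where(band_ok, lo, np.nan)
    hi = np.where(band_ok, hi, np.nan)
    return TDLRSurface(t_grid=t_grid, x_grid=x_grid, log_tdlr=point.log_tdlr,
                       ci_lower=lo, ci_upper=hi, level=level, n_boot=n_eff,
                       seed=seed)
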