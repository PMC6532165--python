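"""Scale-invariant TD-LR via placement values and landmark analysis.

A placement value u(x) is the proportion of an event-free reference population
with marker values strictly greater than x — a scale-free standardization that
lets markers measured in different units be compared on a common [0, 1] axis.
In the survival setting the natural reference population at time s is the risk
set (subjects with Z >= s), which makes the placement value an internal
time-dependent covariate; the usual hazard-survival relationship then breaks
down, so the scale-invariant TD-LR is computed by landmarking: at each
landmark time s, refit KM and Cox on the subjects still at risk at s with
their placement values frozen at s, and evaluate the TD-LR a fixed horizon
ahead (t = s + horizon) on the original time scale conditioned on T >= s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .surface import tdlr_point
from .survival_core import SurvivalDataset, cox_fit, km_estimate

__all__ = ["LandmarkSpec", "PlacementValues", "placement_values",
           "probit_transform", "landmark_tdlr", "landmark_profile"]

DEFAULT_U_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)


@dataclass(frozen=True)
class LandmarkSpec:
    """Landmark times s and a forward horizon; evaluation happens at t = s + horizon."""

    landmark_times: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        s = np.asarray(self.landmark_times, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) < 0):
            raise ValueError("landmark times must be nonnegative and nondecreasing")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        object.__setattr__(self, "landmark_times", s)


@dataclass(frozen=True)
class PlacementValues:
    """Placement values u in [0,1] against a risk-set reference of size m."""

    u: np.ndarray
    reference_size: int
    transformed: Optional[np.ndarray] = None


def placement_values(x_eval, data: SurvivalDataset, s: float, *,
                     ties: str = "strict") -> PlacementValues:
    """u(x) = share of the risk set at s (Z >= s) with marker strictly above x.

    ``ties='midrank'`` counts ties as half (excluding the evaluated point
    itself is not attempted: ties at x each contribute 1/2).
    """
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    ref = data.marker[data.time >= s]
    m = len(ref)
    if m == 0:
        raise ValueError(f"risk set at landmark time s={s} is empty")
    ref_sorted = np.sort(ref)
    n_le = np.searchsorted(ref_sorted, x_eval, side="right")
    greater = (m - n_le).astype(float)
    if ties == "midrank":
        n_lt = np.searchsorted(ref_sorted, x_eval, side="left")
        greater += 0.5 * (n_le - n_lt)
    elif ties != "strict":
        raise ValueError(f"unknown tie policy {ties!r}")
    return PlacementValues(u=greater / m, reference_size=m)


def probit_transform(pv: PlacementValues) -> PlacementValues:
    """Fill ``transformed`` with Phi^{-1}(1 - u), u clipped to [1/(2m), 1 - 1/(2m)].

    The clipping is a continuity correction keeping the transform finite at
    u in {0, 1}; small u (high marker) maps to large positive values.
    """
    m = pv.reference_size
    u = np.clip(pv.u, 1.0 / (2 * m), 1.0 - 1.0 / (2 * m))
    return PlacementValues(u=pv.u, reference_size=m, transformed=norm.ppf(1.0 - u))


def _landmark_fits(data: SurvivalDataset, s: float, *, covariate: str, ties: str):
    """Risk-set subset, its KM and Cox fits on the placement-value scale."""
    mask = data.time >= s
    if not mask.any():
        raise ValueError(f"risk set at landmark time s={s} is empty")
    sub = data.subset(mask)
    if not np.any((sub.event == 1) & (sub.time > s)):
        raise ValueError(f"no events after landmark time s={s}")
    pv = placement_values(sub.marker, sub, 0.0)  # risk set of sub at >=0 is sub itself
    if covariate == "probit":
        cov = probit_transform(pv).transformed
    elif covariate == "raw":
        cov = pv.u
    else:
        raise ValueError(f"unknown covariate scale {covariate!r}")
    if np.ptp(cov) == 0:
        raise ValueError(f"degenerate placement covariate at landmark s={s}")
    lm_data = sub.with_marker(cov)
    km = km_estimate(lm_data)
    model = cox_fit(lm_data, ties=ties)
    return lm_data, km, model, pv.reference_size


def _u_to_covariate(u_grid: np.ndarray, m: int, covariate: str) -> np.ndarray:
    if covariate == "probit":
        u = np.clip(u_grid, 1.0 / (2 * m), 1.0 - 1.0 / (2 * m))
        return norm.ppf(1.0 - u)
    return u_grid


def landmark_tdlr(data: SurvivalDataset, s: float, t: float,
                  u_grid: Sequence[float] = DEFAULT_U_GRID, *,
                  covariate: str = "probit", ties: str = "efron") -> np.ndarray:
    """Scale-invariant log TD-LR at time t for each placement value in u_grid.

    Subjects with Z >= s form the analysis set; each gets its (probit-
    transformed, by default) placement value relative to this risk set as a
    fixed covariate, and KM/Cox are refit on the original time scale
    conditioned on T >= s.  Returns log TD-LR per u (NaN where undefined).
    """
    if t <= s:
        raise ValueError("evaluation time t must exceed the landmark time s")
    u_grid = np.asarray(u_grid, dtype=float)
    if np.any((u_grid < 0) | (u_grid > 1)):
        raise ValueError("u_grid values must lie in [0, 1]")
    _, km, model, m = _landmark_fits(data, s, covariate=covariate, ties=ties)
    cov_grid = _u_to_covariate(u_grid, m, covariate)
    out = np.empty(len(u_grid))
    for j, v in enumerate(cov_grid):
        val = tdlr_point(km, model, t, v)
        out[j] = np.log(val) if np.isfinite(val) else np.nan
    return out


def landmark_profile(data: SurvivalDataset, spec: LandmarkSpec,
                     u_grid: Sequence[float] = DEFAULT_U_GRID, *,
                     covariate: str = "probit", ties: str = "efron",
                     marker_id: str = "marker") -> pd.DataFrame:
    """Scale-invariant log TD-LR at t = s + horizon for each landmark s.

    Failing landmarks (horizon beyond follow-up, empty risk set, no post-s
    events) are skipped with a warning rather than aborting the profile.
    Returns a long table with columns s, u, marker_id, log_tdlr_si; overlay
    two markers by concatenating their profiles.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    rows = []
    t_max = data.time.max()
    for s in spec.landmark_times:
        t = s + spec.horizon
        if t > t_max:
            warnings.warn(f"landmark s={s}: evaluation time {t} exceeds the last "
                          f"observed time {t_max}; skipped", RuntimeWarning, stacklevel=2)
            continue
        try:
            vals = landmark_tdlr(data, s, t, u_grid, covariate=covariate, ties=ties)
        except ValueError as exc:
            warnings.warn(f"landmark s={s} skipped: {exc}", RuntimeWarning, stacklevel=2)
            continue
        for u, v in zip(u_grid, vals):
            rows.append((s, u, marker_id, v))
    return pd.DataFrame(rows, columns=["s", "u", "marker_id", "log_tdlr_si"])
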