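# Methods

## The TD-LR model

For a failure time T, censoring time C, observed time Z = min(T, C), event
indicator δ = 1{T ≤ C} and continuous marker X, define the time-dependent
event status D(t) = 1{T ≤ t}. Bayes' rule turns the likelihood ratio of a
marker value x — the density ratio of X among cases (D(t) = 1) versus
controls (D(t) = 0) — into a ratio of conditional to marginal odds:

TD-LR(x, t) = odds(D(t) = 1 | X = x) / odds(D(t) = 1)
            = [(1 − S(t|x)) / S(t|x)] · [S(t) / (1 − S(t))].

The estimator substitutes the Kaplan–Meier estimate for S(t) and the Cox
proportional-hazards conditional survival Ŝ₀(t)^exp(β̂x) for S(t|x). Its
validity therefore rests on three assumptions: noninformative censoring,
proportional hazards, and log-linearity of the marker effect on the hazard.
A Schoenfeld-residual diagnostic is provided to screen the proportionality
assumption; it is advisory and never blocks estimation.

## Survival primitives

- **Risk sets and steps.** A subject is at risk at s iff Z ≥ s; events at
  exactly s belong to the risk set at s. All step functions are evaluated
  right-continuously, so S(t) at an event time includes that event.
- **Cox fit.** The univariate partial likelihood is maximized by
  Newton–Raphson with step-halving, stopping when |score| < 1e-9 or the
  relative log-likelihood change drops below 1e-12 (at most 100 iterations;
  divergence past |β| = 500 raises, which catches monotone likelihoods).
  Efron tie handling is the default, Breslow optional. The marker is centered
  at its sample mean for numerical stability; conditional survival un-centers
  transparently. The implementation is vectorized because the bootstrap and
  the performance study need tens of thousands of fits; it agrees with
  lifelines and with direct one-dimensional maximization to ~1e-6 (tested).
- **Baseline survival.** Default is the Breslow cumulative hazard with
  Ŝ₀ = exp(−Λ̂₀). The Kalbfleisch–Prentice product-form estimator is available
  as an option; it reduces exactly to Kaplan–Meier at β = 0 with distinct
  event times. Both are kept because the two conventions genuinely differ in
  the literature and either is defensible; the default is a package choice,
  not a claim about which one is "right".
- **PH diagnostic.** Grambsch–Therneau style correlation of scaled Schoenfeld
  residuals with Kaplan–Meier-transformed time, computed by lifelines'
  `proportional_hazard_test` on a refit of the same univariate model.

## Surface estimation and bootstrap

The log TD-LR is computed on a grid: by default 12 equally spaced times
between the 5th and 95th percentiles of observed event times and 21 marker
values between the 2.5th and 97.5th marker percentiles, so default surfaces
never extrapolate beyond the data span. Cells where any survival estimate is
exactly 0 or 1 have undefined odds; they carry NaN and a warning, are never
zero-filled, and are left blank in plots.

Confidence bands are pointwise bootstrap percentiles: subjects are resampled
with replacement, KM and Cox refit per replicate, and the (1−level)/2 and
1−(1−level)/2 quantiles taken per cell over replicates with a defined value.
Replicates with no events or a constant marker are discarded and the
effective count reported. A band is only reported where at least 80% of
effective replicates are defined, which keeps tail cells from being
summarized by a handful of extreme resamples. Each replicate draws from a
deterministically spawned substream of the seed, so results are independent
of execution order. Percentile bands are not forced to contain the point
estimate (they can exclude it in skewed cells); lower ≤ upper always holds.

## Placement values and landmarking

The placement value u(x) at time s is the share of the risk set at s with
marker values strictly above x — a scale-free standardization, invariant
under any strictly increasing marker transform (tested exactly). Ties are
counted strictly by default ("greater than"); a midrank option exists.
Because the risk set changes with survival, the placement value is an
internal time-dependent covariate and plain Cox conditional survival is not
available for it; the package therefore landmarks: at each landmark s it
subsets to Z ≥ s, freezes each subject's placement value relative to that
risk set, refits KM and Cox on the original time scale conditioned on T ≥ s,
and evaluates the TD-LR at t = s + horizon. The Cox covariate is the probit
transform Φ⁻¹(1 − u) by default (raw u optional), with u clipped to
[1/(2m), 1 − 1/(2m)] for a risk set of size m so the transform stays finite
at u ∈ {0, 1}. Landmarks whose horizon exceeds follow-up, or with no post-s
events, are skipped with a warning rather than aborting the profile.

## TD-ROC connection

The cumulative/dynamic TD-ROC at t (cases T ≤ t, controls T > t) is
estimated with conditional Kaplan–Meier weighting: P(X > c, T > t) =
Ŝ(t | X > c) · P̂(X > c) from a KM fit on the X > c subset. With no censoring
this reduces exactly to the empirical binary ROC (tested against
scikit-learn to machine precision). The curve is assembled in threshold
order, where both coordinates are naturally nondecreasing; small local
violations that KM reweighting can produce under censoring are removed by a
monotone (running-maximum) pass. AUC is the trapezoidal integral.

Differentiating the ROC with respect to the false positive rate r gives the
case/control density ratio of the marker, i.e. the TD-LR evaluated at the
marker value whose placement value is r. (One published display labels this
derivative as being with respect to t; the mathematics requires r, and the
package follows the mathematics.) The derivative is estimated by a local
linear fit over FPR with a Gaussian kernel, default bandwidth 0.1 in FPR
units, floored at 0; the numerical identity with `tdlr_point` holds within a
few percent at moderate n (tested at 25% tolerance). Since ROC curves are
concave and tied down at the corners, the marker value where TD-LR ≈ 1
(log TD-LR crosses 0) marks the point nearest the ideal (0, 1) corner;
`optimal_cutoff` finds per-time crossings by linear interpolation and
summarizes them by their median, flagging identically-zero (indeterminate)
rows explicitly.

## Generative model and oracle

Markers are standard normal; event times follow the hazard
λ(t|x) = (1/event_scale)·exp(βx + γtx), with γ = 0 the proportional-hazards
case. Event times are drawn by inverting the closed-form cumulative hazard
a·(e^{γxt} − 1)/(γx) (a = e^{βx}/event_scale), which degenerates smoothly to
a·t at γx = 0, so the PH path and the interaction path with γ = 0 are
bitwise identical. For γx < 0 the cumulative hazard is bounded and a subject
may never fail; such subjects are censored. Censoring times are exponential
with mean `censor_scale`, truncated at `max_followup` (the cap counts as
censoring). Defaults: event scale 7, censoring scale 10, cap 5, β = log 2 —
the event/censoring "7 and 10" are read as scale (mean) parameters.

The oracle TD-LR uses the closed-form conditional survival and integrates
the marginal S(t) = E[S(t|X)] over the standard-normal marker by adaptive
quadrature (verified against a 10⁶-draw Monte-Carlo average to 1e-3).

**Censoring calibration.** The published 10–15% and 60–80% censoring bands do
not pin down a censoring rate, so `calibrate_censoring` bisects the
censoring scale against a 50 000-subject fixed-seed pilot (common random
numbers make the pilot fraction monotone in the scale) until the fraction
hits the band midpoint. Two structural floors matter: with the 5-year cap
and event scale 7, administrative censoring alone is ~47%, so benchmark runs
that need the 10–15% band (and any evaluation at t = 8) set the cap to 100,
effectively uncapped; and under γ = 0.2 the immune fraction keeps censoring
above ~24% regardless, so the non-PH study arm uses the 60–80% band.

**Performance study.** `performance_study` repeats: simulate, fit KM and Cox
once, evaluate the TD-LR at each (t, x), subtract the oracle value; bias and
MSE are reported on both the raw TD-LR and log scales together with
Monte-Carlo standard errors and the count of replicates yielding a defined
estimate. Raw-scale values are used when comparing against published
interior-cell entries, where near-zero bias is scale-robust. The benchmark
script uses 500 replicates at n ∈ {500, 1000}; the trend checks use 200
replicates, and the bootstrap-coverage check uses 200 outer replicates with
200 bootstrap resamples at n = 300 — sizes chosen to keep Monte-Carlo error
comfortably below the effects being measured.

## What the synthetic data does and does not show

The generator reproduces the features the method is sensitive to —
censoring, marker-dependent hazards, administrative follow-up limits, and a
controllable proportionality violation — under a clean exponential baseline
with a normally distributed marker. Real cohorts add features it does not
emulate: non-monotone or nonlinear marker effects, informative censoring,
covariate-dependent censoring, measurement error in the marker, and tied
event times from coarse recording (ties are handled, but the generator never
produces them). Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those violations; the
PH diagnostic and the non-PH study arm show what breaks, and how badly, when
proportionality fails (late times and extreme marker values first).

## Known limitations

- Univariate marker only: no covariate adjustment, stratification, or
  time-varying covariates inside the Cox fit.
- Bands are pointwise percentiles; no simultaneous bands and no analytic
  (delta-method) standard errors.
- The TD-ROC estimator is the conditional-KM one; incident/dynamic and
  IPCW variants are out of scope, as are AUC confidence intervals.
- The partial-likelihood MLE carries O(1/n_events) bias like any Cox fit;
  under very heavy censoring this bias is measurable at n = 1000 (it is a
  property of the estimator, not of this implementation).
- Competing risks and interval censoring are unsupported.
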