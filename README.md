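# tdlr — time-dependent likelihood ratios for survival biomarkers

`tdlr` quantifies the predictive value of a continuous biomarker for a
right-censored survival outcome through the **time-dependent likelihood ratio
(TD-LR)**. For an event indicator D(t) = 1{T ≤ t}, the likelihood ratio of a
marker value x is the multiplicative update it applies to the prevalence-based
odds of the event:

```
TD-LR(x, t) = [(1 − S(t|x)) / S(t|x)] · [S(t) / (1 − S(t))]
```

where S(t) is the marginal survival function and S(t|x) the survival function
conditional on the marker. A value above 1 means the marker value shifts the
odds of failing by time t upward; 1 means the marker is uninformative at that
(x, t). The package is aimed at biostatisticians evaluating prognostic markers
(e.g., in oncology cohorts), where a surface of odds updates over time and
marker value communicates more than a single hazard ratio.

Estimation plugs in the Kaplan–Meier estimate for S(t) and a univariate Cox
proportional-hazards fit for S(t|x) = S₀(t)^exp(βx). The package provides:

- **`tdlr.survival_core`** — Kaplan–Meier, fast univariate Cox partial-likelihood
  fit (Efron or Breslow ties), Breslow and Kalbfleisch–Prentice baseline
  survival, and a Schoenfeld-residual proportional-hazards diagnostic.
- **`tdlr.surface`** — the TD-LR surface over a (time × marker) grid with
  pointwise bootstrap percentile confidence bands.
- **`tdlr.scale_invariant`** — placement-value standardization and landmark
  analysis for comparing markers on different scales.
- **`tdlr.tdroc`** — cumulative/dynamic time-dependent ROC curves, AUC(t), the
  smoothed ROC derivative (which equals the TD-LR at the matching placement
  value), and optimal-cutoff selection where TD-LR ≈ 1.
- **`tdlr.simulate`** — the exponential-hazard generative model with an optional
  time×marker interaction, a quadrature oracle for the true TD-LR, censoring
  calibration, and a bias/MSE performance study.
- **`tdlr` CLI** — `surface`, `landmark`, `roc` and `simulate` subcommands over
  CSV tables with columns `time`, `event` (0/1), `marker`.

## Worked example

```python
import numpy as np
from tdlr import (SimulationConfig, simulate_dataset, cox_fit, km_estimate,
                  tdlr_point, tdlr_fit, true_tdlr)

cfg = SimulationConfig(n=1000, beta=np.log(2.0), seed=5)   # HR = 2 per marker SD
data = simulate_dataset(cfg)
model = cox_fit(data)
km = km_estimate(data)
print(f"beta_hat = {model.beta:.3f} (se {model.se_beta:.3f})")
print(f"TD-LR at t=2, x=+1: {tdlr_point(km, model, 2.0, 1.0):.3f}")
print(f"TD-LR at t=2, x=-1: {tdlr_point(km, model, 2.0, -1.0):.3f}")
print(f"true TD-LR at t=2, x=-1: {true_tdlr(cfg, 2.0, -1.0):.3f}")
```

prints

```
beta_hat = 0.624 (se 0.049)
TD-LR at t=2, x=+1: 1.869
TD-LR at t=2, x=-1: 0.433
true TD-LR at t=2, x=-1: 0.392
```

A subject one standard deviation above the marker mean has their odds of
failing by t = 2 multiplied by about 1.87 relative to the marginal odds; a
subject one SD below has them multiplied by about 0.43, closely tracking the
value implied by the generative model. `tdlr_fit(data)` evaluates the whole
log TD-LR surface, and

```sh
tdlr surface cohort.csv -o out/ --n-boot 1000 --seed 1
```

writes the surface table, 3-D and contour figures, bootstrap bands, and a
reproducibility manifest.

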