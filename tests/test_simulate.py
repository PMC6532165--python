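"""Data-generating process, censoring calibration, the true-TD-LR oracle,
and the bias/MSE performance machinery."""

import numpy as np
import pytest

from tdlr import (SimulationConfig, calibrate_censoring, cox_fit,
                  normality_check, performance_study, replicate_errors,
                  simulate_dataset, true_tdlr)
from tdlr.simulate import conditional_survival_true, marginal_survival_true


class TestSimulateDataset:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(n=200, seed=5)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.event, b.event)
        assert np.array_equal(a.marker, b.marker)

    def test_gamma_zero_paths_identical(self):
        a = simulate_dataset(SimulationConfig(n=500, gamma=0.0, seed=7))
        b = simulate_dataset(SimulationConfig(n=500, gamma=0.2, seed=7)
                             .replace(gamma=0.0))
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.event, b.event)

    def test_censoring_fraction_stable_across_batches(self):
        """MC stability of the censoring fraction at the default rates."""
        cfg = SimulationConfig(n=1000, beta=0.0, gamma=0.0)
        fracs = [simulate_dataset(cfg.replace(seed=100 + r)).censoring_fraction
                 for r in range(200)]
        fracs = np.asarray(fracs)
        assert np.all(np.abs(fracs - fracs.mean()) < 0.06)
        assert fracs.std() < 0.02

    def test_cap_counts_as_censoring(self):
        cfg = SimulationConfig(n=2000, censor_scale=1e9, max_followup=2.0, seed=3)
        data = simulate_dataset(cfg)
        at_cap = data.time == 2.0
        assert at_cap.any()
        assert np.all(data.event[at_cap] == 0)

    def test_beta_recovered_at_large_n(self):
        data = simulate_dataset(SimulationConfig(n=5000, seed=11))
        fit = cox_fit(data)
        assert abs(fit.beta - np.log(2.0)) < 2 * fit.se_beta


class TestCalibrateCensoring:
    @pytest.mark.parametrize("band", [(0.10, 0.15), (0.60, 0.80)])
    def test_band_hit(self, band):
        cfg = SimulationConfig(n=1000, max_followup=100.0, seed=1)
        scale = calibrate_censoring(cfg, band)
        frac = simulate_dataset(cfg.replace(n=50_000, censor_scale=scale,
                                            seed=12345)).censoring_fraction
        assert band[0] <= frac <= band[1]

    def test_monotone_in_rate(self):
        cfg = SimulationConfig(n=30_000, max_followup=100.0, seed=2)
        fracs = [simulate_dataset(cfg.replace(censor_scale=s)).censoring_fraction
                 for s in (2.0, 10.0, 50.0)]
        assert fracs[0] > fracs[1] > fracs[2]

    def test_unreachable_band_rejected(self):
        cfg = SimulationConfig(n=1000, max_followup=5.0, seed=1)  # cap floor ~0.47
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_censoring(cfg, (0.01, 0.02))


class TestTrueTdlr:
    def test_uninformative_marker_gives_exactly_one(self):
        cfg = SimulationConfig(beta=0.0)
        for t, x in [(1.0, -2.0), (2.0, 0.0), (4.0, 1.5)]:
            assert true_tdlr(cfg, t, x) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_increasing_in_x(self):
        cfg = SimulationConfig(beta=np.log(2.0))
        vals = [true_tdlr(cfg, 2.0, x) for x in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(vals) > 0)

    def test_quadrature_matches_monte_carlo(self):
        cfg = SimulationConfig(beta=np.log(2.0))
        rng = np.random.default_rng(0)
        xs = rng.standard_normal(10 ** 6)
        for t in (1.0, 2.0, 4.0):
            mc = np.mean(np.exp(-np.exp(cfg.beta * xs) * t / cfg.event_scale))
            assert marginal_survival_true(cfg, t) == pytest.approx(mc, abs=1e-3)

    def test_reconstruction_identity_exact(self):
        cfg = SimulationConfig(beta=np.log(2.0), gamma=0.1, max_followup=100.0)
        for t, x in [(1.0, -1.0), (2.0, 0.5), (4.0, 1.0)]:
            lr = true_tdlr(cfg, t, x)
            s_c = conditional_survival_true(cfg, t, x)
            s_m = marginal_survival_true(cfg, t)
            assert (1 - s_c) / s_c == pytest.approx(lr * (1 - s_m) / s_m, rel=1e-12)

    def test_degenerate_time_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            true_tdlr(SimulationConfig(), 1e9, 0.0)


class TestPerformanceStudy:
    def test_single_replicate_definitions(self):
        cfg = SimulationConfig(n=400, seed=9, n_reps=1, max_followup=100.0,
                               censor_scale=58.0)
        table = performance_study([cfg], [(2.0, 0.0)])
        row = table.iloc[0]
        errs = replicate_errors(cfg, [(2.0, 0.0)])
        err = errs["err_raw"].iloc[0]
        assert row["bias_raw"] == pytest.approx(err)
        assert row["mse_raw"] == pytest.approx(err ** 2)
        assert row["n_effective"] == 1

    def test_mse_dominates_squared_bias(self):
        cfg = SimulationConfig(n=300, seed=17, n_reps=50, max_followup=100.0,
                               censor_scale=58.0)
        table = performance_study([cfg], [(2.0, -1.0), (2.0, 1.0)])
        for _, row in table.iterrows():
            assert row["mse_raw"] >= row["bias_raw"] ** 2 - 1e-12
            assert row["mse_log"] >= row["bias_log"] ** 2 - 1e-12

    def test_model_labels_and_bands(self):
        cfgs = [SimulationConfig(n=200, seed=1, n_reps=2, max_followup=100.0),
                SimulationConfig(n=200, seed=1, n_reps=2, gamma=0.2,
                                 max_followup=100.0)]
        table = performance_study(cfgs, [(2.0, 0.0)], bands=["10-15%", "10-15%"])
        assert list(table["model"]) == ["PH", "nonPH"]
        assert set(table["cens_band"]) == {"10-15%"}


class TestNormalityCheck:
    def test_interior_point_approximately_normal(self, tmp_path):
        cfg = SimulationConfig(n=1000, seed=23, n_reps=200, max_followup=100.0,
                               censor_scale=58.0)
        out = normality_check(cfg, [(2.0, 0.0)], output_dir=tmp_path)
        assert abs(out["skewness"].iloc[0]) < 0.5
        assert (tmp_path / "tdlr_hist_t2_x0.png").exists()

    def test_extreme_point_has_heavier_tails(self):
        cfg = SimulationConfig(n=100, seed=29, n_reps=200, max_followup=100.0,
                               censor_scale=58.0)
        out = normality_check(cfg, [(2.0, 0.0), (8.0, 1.5)])
        kurt = out.set_index(["t", "x"])["kurtosis"]
        assert kurt[(8.0, 1.5)] > kurt[(2.0, 0.0)]

    def test_requires_enough_replicates(self):
        with pytest.raises(ValueError, match="200"):
            normality_check(SimulationConfig(n_reps=50), [(2.0, 0.0)])
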