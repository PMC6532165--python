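"""Kaplan-Meier, Cox partial likelihood, baseline survival and the PH check."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from tdlr import (ConvergenceError, SurvivalDataset, baseline_survival,
                  conditional_survival, cox_fit, km_estimate,
                  log_partial_likelihood, ph_diagnostic, simulate_dataset,
                  survival_at, SimulationConfig)
from tdlr.survival_core import StepSurvivalCurve


class TestSurvivalDataset:
    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError, match="finite and > 0"):
            SurvivalDataset([0.0, 1.0], [1, 1], [0.0, 1.0])

    def test_rejects_non_binary_events(self):
        with pytest.raises(ValueError, match="0/1"):
            SurvivalDataset([1.0, 2.0], [1, 2], [0.0, 1.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            SurvivalDataset([1.0, 2.0], [1], [0.0, 1.0])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate(SurvivalDataset([1, 2, 3], [1, 1, 1], [0.0, 1.0, 2.0]))
        assert np.allclose(km.surv_probs, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_degenerate(self):
        with pytest.raises(ValueError, match="censored"):
            km_estimate(SurvivalDataset([1, 2], [0, 0], [0.0, 1.0]))

    def test_product_limit_with_censoring(self):
        # events at 2 and 3; risk sets of size 3 and 2: S(2)=2/3, S(3)=1/3
        km = km_estimate(SurvivalDataset([1, 2, 3, 4], [0, 1, 1, 0],
                                         [0.0, 1.0, 2.0, 3.0]))
        assert survival_at(km, 2) == pytest.approx(2 / 3)
        assert survival_at(km, 3) == pytest.approx(1 / 3)

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=40))
    def test_uncensored_km_is_empirical_everywhere(self, times):
        times = np.asarray(times, dtype=float)
        data = SurvivalDataset(times, np.ones(len(times), int), np.zeros(len(times)))
        km = km_estimate(data)
        for t in np.unique(times):
            assert survival_at(km, t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_matches_lifelines(self, ph_data):
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(ph_data.time, ph_data.event)
        km = km_estimate(ph_data)
        theirs = kmf.survival_function_at_times(km.jump_times).to_numpy()
        assert np.allclose(km.surv_probs, theirs, atol=1e-12)


class TestSurvivalAt:
    @pytest.fixture
    def curve(self):
        return StepSurvivalCurve([2.0, 3.0], [2 / 3, 1 / 3], [3, 2])

    def test_one_before_first_jump(self, curve):
        assert survival_at(curve, 0.0) == 1.0

    def test_right_continuous_at_jump(self, curve):
        assert survival_at(curve, 2.0) == pytest.approx(2 / 3)

    def test_constant_between_jumps_and_after_last(self, curve):
        assert survival_at(curve, 2.5) == pytest.approx(2 / 3)
        assert survival_at(curve, 99.0) == pytest.approx(1 / 3)

    def test_negative_time_rejected(self, curve):
        with pytest.raises(ValueError):
            survival_at(curve, -0.1)


class TestCoxFit:
    def test_sign_antisymmetry(self, tiny_data):
        m_pos = cox_fit(tiny_data)
        m_neg = cox_fit(tiny_data.with_marker(-tiny_data.marker))
        assert m_neg.beta == pytest.approx(-m_pos.beta, abs=1e-8)
        assert m_neg.log_partial_likelihood == pytest.approx(
            m_pos.log_partial_likelihood, abs=1e-10)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_bruteforce_partial_likelihood_maximum(self, tiny_data, ties):
        fit = cox_fit(tiny_data, ties=ties)
        res = minimize_scalar(
            lambda b: -log_partial_likelihood(tiny_data, b, ties=ties),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-12})
        assert fit.beta == pytest.approx(res.x, abs=1e-6)

    def test_bruteforce_agreement_on_tied_two_group_data(self):
        data = SurvivalDataset([1, 1, 2, 3, 3, 4, 5, 6],
                               [1, 1, 0, 1, 1, 1, 0, 1],
                               [1, 1, 0, 1, 0, 0, 1, 0])
        fit = cox_fit(data)
        res = minimize_scalar(lambda b: -log_partial_likelihood(data, b),
                              bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-12})
        assert fit.beta == pytest.approx(res.x, abs=1e-6)

    def test_matches_lifelines_estimate_and_se(self, ph_data):
        from lifelines import CoxPHFitter
        import pandas as pd
        df = pd.DataFrame({"T": ph_data.time, "E": ph_data.event,
                           "x": ph_data.marker})
        cph = CoxPHFitter().fit(df, "T", "E")
        fit = cox_fit(ph_data)
        assert fit.beta == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.se_beta == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-4)

    def test_null_marker_beta_within_three_se(self, null_data_large):
        fit = cox_fit(null_data_large)
        assert abs(fit.beta) < 3 * fit.se_beta

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(SurvivalDataset([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0]))

    def test_parameter_recovery(self):
        """Mean beta-hat over replicates lies within 2 MC-SE of log 2.

        Run at the 10-15% censoring band; under very heavy censoring the
        genuine O(1/n_events) bias of the partial-likelihood MLE (shared by
        any correct implementation) exceeds Monte-Carlo noise at 200 reps.
        """
        from tdlr import calibrate_censoring
        base = SimulationConfig(n=1000, max_followup=100.0)
        sc = calibrate_censoring(base, (0.10, 0.15))
        betas = []
        for rep in range(200):
            data = simulate_dataset(base.replace(censor_scale=sc, seed=1000 + rep))
            betas.append(cox_fit(data).beta)
        betas = np.asarray(betas)
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - np.log(2.0)) < 2 * se


class TestBaselineSurvival:
    def test_beta_zero_kp_baseline_equals_km(self, ph_data):
        fit = cox_fit(ph_data)
        fit0 = dataclasses.replace(fit, beta=0.0)
        kp = baseline_survival(fit0, ph_data, method="kalbfleisch-prentice")
        km = km_estimate(ph_data)
        assert np.allclose(kp.surv_probs, km.surv_probs, atol=1e-14)

    def test_breslow_hand_computation_single_event(self):
        # event at t=2 among 4 at-risk subjects; Lambda0(2) = 1 / sum_risk w_i
        data = SurvivalDataset([1.0, 2.0, 3.0, 4.0, 5.0], [0, 1, 0, 1, 0],
                               [0.2, -0.3, 0.8, -0.1, 0.4])
        fit = cox_fit(data)
        w = np.exp(fit.beta * (data.marker - fit.marker_center))
        expected = 1.0 / w[data.time >= 2.0].sum()
        assert fit.baseline_cumhaz(2.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("method", ["breslow", "kalbfleisch-prentice"])
    def test_baseline_monotone_non_increasing(self, ph_data, method):
        fit = cox_fit(ph_data)
        curve = baseline_survival(fit, ph_data, method=method)
        assert np.all(np.diff(curve.surv_probs) <= 1e-15)

    def test_breslow_consistent_with_cumhaz(self, ph_data):
        fit = cox_fit(ph_data)
        assert np.allclose(fit.baseline_curve.surv_probs,
                           np.exp(-fit.baseline_cumhaz.values), atol=1e-14)


class TestConditionalSurvival:
    def test_center_gives_baseline(self, ph_data):
        fit = cox_fit(ph_data)
        t = 2.0
        assert conditional_survival(fit, t, fit.marker_center) == pytest.approx(
            survival_at(fit.baseline_curve, t))

    def test_power_formula(self, ph_data):
        fit = cox_fit(ph_data)
        fit2 = dataclasses.replace(fit, beta=np.log(2.0))
        s0 = survival_at(fit2.baseline_curve, 2.0)
        assert conditional_survival(fit2, 2.0, fit2.marker_center + 1.0) == \
            pytest.approx(s0 ** 2)

    def test_monotone_in_marker_with_beta_sign(self, ph_data):
        fit = cox_fit(ph_data)
        xs = np.linspace(-2, 2, 9)
        s = conditional_survival(fit, 2.0, xs)
        assert fit.beta > 0 and np.all(np.diff(s) < 0)
        flipped = dataclasses.replace(fit, beta=-fit.beta)
        assert np.all(np.diff(conditional_survival(flipped, 2.0, xs)) > 0)


class TestPHDiagnostic:
    def test_requires_five_events(self):
        data = SurvivalDataset([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 0, 0],
                               [0.1, 0.5, -0.2, 0.9, -0.6, 0.3])
        with pytest.raises(ValueError, match="5 events"):
            ph_diagnostic(cox_fit(data), data)

    def test_type_i_error_near_nominal_under_ph(self):
        rejections = 0
        reps = 60
        for rep in range(reps):
            data = simulate_dataset(SimulationConfig(n=300, seed=3000 + rep))
            p = ph_diagnostic(cox_fit(data), data).p_value
            rejections += p < 0.05
        assert rejections / reps < 0.15  # ~0.05 nominal, MC slack at 60 reps

    def test_power_against_time_marker_interaction(self):
        rejections = 0
        reps = 40
        for rep in range(reps):
            data = simulate_dataset(
                SimulationConfig(n=500, gamma=0.8, seed=4000 + rep))
            p = ph_diagnostic(cox_fit(data), data).p_value
            rejections += p < 0.05
        assert rejections / reps > 0.5
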