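"""Skill-learning metrics: arithmetic oracles, closed forms, invariances."""

import numpy as np
import pandas as pd
import pytest

from betarebound import behavior
from betarebound.tracking import segment_blocks


def records_from(errors, set_size=50, block_size=25):
    seg = segment_blocks(len(errors), set_size, block_size)
    seg["error_deg"] = np.asarray(errors, dtype=float)
    return seg


class TestLearningCurve:
    def test_constant_errors_give_flat_curve(self):
        curve = behavior.learning_curve(records_from(np.full(300, 10.0)))
        assert np.allclose(curve, 10.0)
        assert len(curve) == 12

    def test_absolute_value_taken_before_mean(self):
        rec = records_from(np.tile([-4.0, 4.0], 25), set_size=50, block_size=25)
        assert np.allclose(behavior.learning_curve(rec), 4.0)

    def test_decay_constant_recovered_from_synthetic_cohort(self):
        """Fitting the block curve of generated errors recovers the
        programmed decay constant within 20%."""
        from scipy.optimize import curve_fit

        from betarebound.synth import ErrorCurve, generate_error_series

        curve = ErrorCurve(initial_bias=12.0, plateau_bias=2.0, initial_sd=0.5,
                           plateau_sd=0.5, decay_constant=40.0, ar1_rho=0.0)
        rng = np.random.default_rng(0)
        fits = []
        for _ in range(10):
            e = generate_error_series(curve, 300, rng)
            blocks = behavior.learning_curve(records_from(e)).to_numpy()
            centers = np.arange(12) * 25 + 12.5

            def model(t, a, b, tau):
                return b + a * np.exp(-t / tau)

            popt, _ = curve_fit(model, centers, blocks, p0=(10, 2, 30), maxfev=10000)
            fits.append(popt[2])
        assert np.mean(fits) == pytest.approx(40.0, rel=0.2)


class TestLearningRate:
    def test_arithmetic(self):
        e = np.concatenate([np.full(25, 10.0), np.full(175, 7.0), np.full(100, 4.0)])
        assert behavior.learning_rate(records_from(e)) == pytest.approx(0.6)

    def test_no_improvement_is_zero(self):
        assert behavior.learning_rate(records_from(np.full(300, 5.0))) == pytest.approx(0.0)

    def test_worsening_gives_unclamped_negative_rate(self):
        e = np.concatenate([np.full(200, 4.0), np.full(100, 10.0)])
        assert behavior.learning_rate(records_from(e)) == pytest.approx(-1.5)

    def test_zero_initial_error_reported_missing(self):
        e = np.concatenate([np.zeros(25), np.full(275, 1.0)])
        assert np.isnan(behavior.learning_rate(records_from(e)))


class TestVariability:
    def test_constant_errors_zero_sd_and_decay(self):
        rec = records_from(np.full(300, 3.0))
        assert np.allclose(behavior.intertrial_variability(rec), 0.0)
        assert behavior.variability_decay(rec) == pytest.approx(0.0)

    def test_two_point_block_sample_sd(self):
        # {-1, 1}: sample SD with n-1 denominator is sqrt(2)
        rec = records_from(np.array([-1.0, 1.0]), set_size=2, block_size=2)
        assert behavior.intertrial_variability(rec).iloc[0] == pytest.approx(np.sqrt(2))

    def test_single_trial_block_fails(self):
        rec = records_from(np.array([1.0, 2.0]), set_size=1, block_size=1)
        with pytest.raises(ValueError):
            behavior.intertrial_variability(rec)


class TestTrialChange:
    def test_constant_errors_zero(self):
        assert np.allclose(behavior.trial_to_trial_change(records_from(np.full(300, 2.0))), 0.0)

    def test_hand_case(self):
        rec = records_from(np.array([0.0, 2.0, -2.0]), set_size=3, block_size=3)
        assert behavior.trial_to_trial_change(rec).iloc[0] == pytest.approx(3.0)

    def test_iid_closed_form(self):
        # |e_t - e_{t-1}| ~ |N(0, 2 sigma^2)|, expectation 2 sigma / sqrt(pi)
        sigma = 3.0
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            e = rng.normal(0, sigma, 300)
            vals.append(behavior.trial_to_trial_change(records_from(e)).mean())
        assert np.mean(vals) == pytest.approx(2 * sigma / np.sqrt(np.pi), rel=0.02)

    def test_change_stays_within_blocks(self):
        # a large jump across the block boundary must not contaminate
        e = np.concatenate([np.zeros(25), np.full(25, 100.0)])
        rec = records_from(e, set_size=50, block_size=25)
        assert np.allclose(behavior.trial_to_trial_change(rec), 0.0)


class TestACF:
    def test_alternating_series_is_minus_one(self):
        rec = records_from(np.tile([1.0, -1.0], 150))
        a1, a2, decay = behavior.acf1_halves(rec)
        assert a1 == pytest.approx(-1.0)
        assert a2 == pytest.approx(-1.0)
        assert decay == pytest.approx(0.0)

    def test_white_noise_null_band(self):
        rng = np.random.default_rng(2)
        inside = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = behavior.acf1(rng.normal(0, 1, 150))
            if abs(a) < 2 / np.sqrt(150):
                inside += 1
        assert inside >= 0.90 * n_sim

    def test_ar1_recovery_within_bias_envelope(self):
        # ACF(1) of an AR(1) with rho = 0.5 at n = 150: known small-sample
        # downward bias of roughly (1 + 3 rho)/n
        rho, n = 0.5, 150
        rng = np.random.default_rng(3)
        est = []
        for _ in range(1000):
            x = np.empty(n)
            x[0] = rng.normal()
            for i in range(1, n):
                x[i] = rho * x[i - 1] + rng.normal(0, np.sqrt(1 - rho**2))
            est.append(behavior.acf1(x))
        expected = rho - (1 + 3 * rho) / n
        assert np.mean(est) == pytest.approx(expected, abs=0.02)

    def test_time_reversal_symmetry(self, rng):
        x = rng.normal(0, 1, 200).cumsum()
        assert behavior.acf1(x) == pytest.approx(behavior.acf1(x[::-1]))


class TestComplexity:
    def test_isotropic_data_near_one(self, rng):
        X = rng.standard_normal((5000, 8))
        assert behavior.manipulative_complexity(X) >= 0.95

    def test_rank_one_data_is_zero(self, rng):
        z = rng.standard_normal(500)
        X = np.outer(z, np.ones(6))
        assert behavior.manipulative_complexity(X) == pytest.approx(0.0, abs=1e-9)

    def test_half_split_hand_case(self, rng):
        # eigenvalue proportions {0.5, 0.5, 0, 0} with N = 4: C = ln2/ln4 = 0.5
        n = 200000
        X = np.zeros((n, 4))
        X[:, 0] = rng.standard_normal(n)
        X[:, 1] = rng.standard_normal(n)
        assert behavior.manipulative_complexity(X) == pytest.approx(0.5, abs=0.01)

    def test_invariance_to_reordering_and_scaling(self, rng):
        X = rng.standard_normal((400, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.2])
        c = behavior.manipulative_complexity(X)
        perm = rng.permutation(6)
        assert behavior.manipulative_complexity(X[:, perm]) == pytest.approx(c, abs=1e-9)
        assert behavior.manipulative_complexity(7.3 * X) == pytest.approx(c, abs=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            behavior.manipulative_complexity(np.zeros((100, 4)))
        with pytest.raises(ValueError):
            behavior.manipulative_complexity(rng.standard_normal((3, 5)))


class TestHeadMovement:
    def test_zero_acceleration_zero_peaks(self):
        times = np.linspace(-1, 3, 400)
        out = behavior.head_movement_summary(np.zeros((4, 400)), times, np.ones(4, int))
        assert np.allclose(out["peak_accel"], 0.0)

    def test_spike_inside_window_is_the_peak(self):
        times = np.linspace(-1, 3, 400)
        acc = np.zeros((1, 400))
        acc[0, np.argmin(np.abs(times - 1.0))] = -5.0  # magnitude counts
        out = behavior.head_movement_summary(acc, times, np.array([1]))
        assert out["peak_accel"].iloc[0] == pytest.approx(5.0)

    def test_spike_outside_window_excluded(self):
        times = np.linspace(-1, 3, 400)
        acc = np.zeros((1, 400))
        acc[0, np.argmin(np.abs(times + 0.5))] = 9.0  # pre-offset
        out = behavior.head_movement_summary(acc, times, np.array([1]))
        assert out["peak_accel"].iloc[0] == pytest.approx(0.0)
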