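"""Trace processing: rejection, blank subtraction, windows, differentiation."""

import numpy as np
import pytest

from ofr_brf import StimulusCondition
from ofr_brf import defaults as d
from ofr_brf.synthetic import EyeTrace, simulate_trial
from ofr_brf.traces import (build_summation_curve, first_acceleration_peak,
                            mean_blank_profile, merge_small_diameter_curve,
                            position_change, reject_trials,
                            velocity_and_acceleration)
from conftest import noiseless_disk_curve


def _trace(x, trial_id=0, condition=None):
    t = np.arange(-100, 250, dtype=float)
    return EyeTrace(t=t, x=np.asarray(x, float), y=np.zeros_like(t),
                    condition=condition, trial_id=trial_id)


def _flat(val=0.0):
    return _trace(np.full(350, val))


class TestRejectTrials:
    def test_clean_noiseless_session_keeps_all(self, exp1_noiseless_session):
        kept, log = reject_trials(exp1_noiseless_session.traces)
        assert len(log) == 0
        assert len(kept) == len(exp1_noiseless_session)

    def test_injected_step_rejected_as_saccade(self):
        t = np.arange(-100, 250, dtype=float)
        x = np.where(t >= 100, 3.0, 0.0)  # 3 deg in 1 ms >> 100 deg/s
        kept, log = reject_trials([_trace(x)])
        assert not kept and log[0]["reason"] == "saccade"

    def test_prestimulus_offset_rejected_as_fixation_break(self):
        kept, log = reject_trials([_flat(1.5)])
        assert not kept and log[0]["reason"] == "fixation_break"

    def test_limits_must_be_positive(self):
        with pytest.raises(ValueError):
            reject_trials([_flat()], fixation_limit=0)


class TestBlankProfile:
    def test_noiseless_blanks_give_zero_profile(self):
        t, mean_x, prof = mean_blank_profile([_flat(), _flat()])
        np.testing.assert_allclose(mean_x, 0.0)
        np.testing.assert_allclose(prof.v, 0.0)

    def test_opposite_slopes_cancel(self):
        t = np.arange(-100, 250, dtype=float)
        up, down = _trace(0.01 * t), _trace(-0.01 * t)
        _, mean_x, _ = mean_blank_profile([up, down])
        np.testing.assert_allclose(mean_x, 0.0, atol=1e-15)

    def test_common_slope_is_preserved(self):
        t = np.arange(-100, 250, dtype=float)
        _, mean_x, prof = mean_blank_profile([_trace(0.02 * t)] * 3)
        np.testing.assert_allclose(np.diff(mean_x), 0.02, atol=1e-12)
        assert prof.n == 3

    def test_no_catch_trials_is_an_error(self):
        with pytest.raises(ValueError, match="catch"):
            mean_blank_profile([])


class TestPositionChange:
    def test_linear_trace(self):
        t = np.arange(-100, 250, dtype=float)
        v = 2.0  # deg/s
        m = position_change(_trace(v * t * 1e-3), (90, 100))
        assert m.mean_dx == pytest.approx(v * 0.010, abs=1e-12)

    def test_trace_equal_to_blank_mean_gives_zero(self):
        t = np.arange(-100, 250, dtype=float)
        x = 0.05 * np.sin(t / 40)
        m = position_change(_trace(x), (60, 70), blank=(t, x))
        assert m.mean_dx == pytest.approx(0.0, abs=1e-15)

    def test_window_outside_trace_raises(self):
        with pytest.raises(ValueError):
            position_change(_flat(), (240, 260))

    def test_common_drift_cancels_blank_subtraction(self, noiseless_truth):
        """Adding an identical drift to stimulus and catch trials leaves the
        blank-corrected amplitude unchanged."""
        cond = StimulusCondition("disk", 14.2, 0.0, 0.36, 30.0, "rightward")
        tr = simulate_trial(cond, noiseless_truth, np.random.default_rng(0))
        base = position_change(tr, d.REFERENCE_WINDOW).mean_dx
        drift = 0.3 * tr.t * 1e-3
        drifted = _trace(tr.x + drift, condition=cond)
        blank = (tr.t, drift.copy())
        m = position_change(drifted, d.REFERENCE_WINDOW, blank)
        assert m.mean_dx == pytest.approx(base, abs=1e-12)


class TestDifferentiation:
    t = np.arange(0, 200, dtype=float)

    def test_constant_and_linear(self):
        v, a = velocity_and_acceleration(self.t, np.full(200, 3.0))
        np.testing.assert_allclose(v, 0.0, atol=1e-9)
        np.testing.assert_allclose(a, 0.0, atol=1e-6)
        v, a = velocity_and_acceleration(self.t, 5.0 * self.t * 1e-3)
        np.testing.assert_allclose(v, 5.0, atol=1e-9)
        np.testing.assert_allclose(a[1:-1], 0.0, atol=1e-6)

    def test_quadratic_recovers_acceleration_exactly(self):
        # central differences are exact for quadratics; the acceleration's
        # interior excludes the samples touched by the one-sided endpoints
        a0 = 40.0  # deg/s^2
        x = 0.5 * a0 * (self.t * 1e-3) ** 2
        v, a = velocity_and_acceleration(self.t, x)
        np.testing.assert_allclose(v[1:-1], a0 * self.t[1:-1] * 1e-3, rtol=1e-9)
        np.testing.assert_allclose(a[2:-2], a0, rtol=1e-9)

    def test_differentiating_exact_antiderivative_is_second_order(self):
        # round trip through a smooth velocity profile: error is O(h^2)
        omega = 2 * np.pi * 5  # 5 Hz modulation
        ts = self.t * 1e-3
        v_true = 10.0 * np.sin(omega * ts)
        x = -10.0 / omega * np.cos(omega * ts)
        v, _ = velocity_and_acceleration(self.t, x)
        bound = 10.0 * omega**2 * (1e-3) ** 2 / 6  # |v''| h^2 / 6
        assert np.max(np.abs(v[1:-1] - v_true[1:-1])) < 1.1 * bound

    def test_operators_are_linear(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=(2, 200))
        v12, a12 = velocity_and_acceleration(self.t, 2 * x1 + 3 * x2)
        v1, a1 = velocity_and_acceleration(self.t, x1)
        v2, a2 = velocity_and_acceleration(self.t, x2)
        np.testing.assert_allclose(v12, 2 * v1 + 3 * v2, atol=1e-8)
        np.testing.assert_allclose(a12, 2 * a1 + 3 * a2, atol=1e-5)

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            velocity_and_acceleration(self.t[:2], np.zeros(2))


class TestFirstAccelerationPeak:
    t = np.arange(0, 200, dtype=float)

    def test_sine_bump(self):
        a = np.where((self.t >= 60) & (self.t <= 100),
                     np.sin(np.pi * (self.t - 60) / 40), 0.0) * 50
        val, when, flag = first_acceleration_peak(self.t, a)
        assert when == 80 and val == pytest.approx(50.0) and not flag

    def test_monotone_has_no_local_max(self):
        val, when, flag = first_acceleration_peak(self.t, self.t * 1.0)
        assert flag and when == self.t[-1]

    def test_tie_breaks_earliest(self):
        a = np.zeros_like(self.t)
        a[70], a[90] = 5.0, 5.0
        _, when, flag = first_acceleration_peak(self.t, a)
        assert when == 70 and not flag


class TestSummationCurves:
    def test_noiseless_exp1_curve_amplitudes(self, exp1_noiseless_session):
        curves = build_summation_curve(exp1_noiseless_session, "disk",
                                       d.REFERENCE_WINDOW)
        assert {c.direction for c in curves} == {"leftward", "rightward"}
        for c in curves:
            assert len(c.diameters) == 12
            assert np.all(np.diff(c.diameters) > 0)
            assert np.all(c.amp >= 0)  # magnitude convention

    def test_noiseless_amplitudes_independent_of_n_trials(self, noiseless_truth):
        from ofr_brf import make_condition_grid, simulate_session
        grid = [c for c in make_condition_grid(1) if c.shape == "disk"]
        a = build_summation_curve(simulate_session(grid, noiseless_truth, 1, 0, 1),
                                  "disk", d.REFERENCE_WINDOW)
        b = build_summation_curve(simulate_session(grid, noiseless_truth, 3, 0, 2),
                                  "disk", d.REFERENCE_WINDOW)
        np.testing.assert_allclose(a[0].amp, b[0].amp, atol=1e-15)
        assert b[0].n[0] == 3 * a[0].n[0]

    def test_merge_small_diameter_set_gives_16_points(self):
        main = noiseless_disk_curve(1.41)
        small = noiseless_disk_curve(1.41, diameters=d.SMALL_DIAMETERS)
        # a different session gain: merging must rescale it away at 7.1 deg
        small = small.rescaled(1.7)
        merged = merge_small_diameter_curve(main, small)
        assert len(merged.diameters) == 16
        assert np.all(np.diff(merged.diameters) > 0)
        # after rescaling, the joined points sit on the main curve's scale
        expected = noiseless_disk_curve(
            1.41, diameters=merged.diameters).amp
        np.testing.assert_allclose(merged.amp, expected, rtol=1e-12)
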