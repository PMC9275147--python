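"""Generator contracts: condition grids, amplitude laws, trial simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ofr_brf import (BRFTruth, StimulusCondition, amplitude_law, default_truth,
                     make_condition_grid, simulate_session, simulate_trial,
                     simulate_window_amplitudes, temporal_frequency)
from ofr_brf import defaults as d
from ofr_brf.models import DoGParams, ExpDecayParams, dog_summation_response
from ofr_brf.synthetic import frame_to_session, session_to_frame
from ofr_brf.traces import build_summation_curve


@pytest.mark.parametrize("sf,speed,tf", [(0.36, 30, 10.8), (1.41, 30, 42.3),
                                         (0.36, 45, 16.2), (0.12, 30, 3.6)])
def test_temporal_frequency(sf, speed, tf):
    assert temporal_frequency(sf, speed) == pytest.approx(tf, abs=1e-12)


def test_temporal_frequency_rejects_nonpositive():
    with pytest.raises(ValueError):
        temporal_frequency(0, 30)


@pytest.mark.parametrize("experiment,n", [("1", 48), (1, 48), ("2", 72),
                                          ("3", 288), ("3s", 36), ("4", 24)])
def test_grid_counts(experiment, n):
    grid = make_condition_grid(experiment)
    assert len(grid) == n
    # fully crossed with both directions
    assert sum(c.direction == "rightward" for c in grid) == n // 2


def test_grid_rejects_unknown_experiment():
    with pytest.raises(ValueError):
        make_condition_grid("5")


def test_condition_invariants():
    c = StimulusCondition("ring", 60.0, 10.65, 0.36, 30.0, "leftward")
    assert c.tf == pytest.approx(c.sf * c.speed, abs=1e-9)
    with pytest.raises(ValueError):
        StimulusCondition("disk", 10.0, 5.0, 0.36, 30.0, "leftward")
    with pytest.raises(ValueError):
        StimulusCondition("ring", 10.0, 10.0, 0.36, 30.0, "leftward")


def test_amplitude_law_limits(truth):
    zero = StimulusCondition("disk", 1e-12, 0.0, 0.36, 30.0, "rightward")
    assert amplitude_law(zero, truth) == pytest.approx(0.0, abs=1e-12)
    # ring at inner diameter ~0 gives g_r + r_0
    p = truth.decay_for(0.36)
    ring0 = StimulusCondition("ring", 60.0, 1e-12, 0.36, 30.0, "rightward")
    assert amplitude_law(ring0, truth) == pytest.approx(p.g_r + p.r_0, rel=1e-9)


def test_amplitude_law_disk_peaks_then_declines(truth):
    """The DoG summation law rises to an optimal size in the 10-20 deg
    range, then declines toward g_e - g_i (dense-grid evaluation of the erf
    expression)."""
    p = truth.dog_for(0.36)
    D = np.arange(0.0, 200.0, 0.01)
    r = dog_summation_response(D, p)
    peak = D[np.argmax(r)]
    assert 10 <= peak <= 20
    assert r[-1] == pytest.approx(p.g_e - p.g_i, rel=1e-4)
    assert r.max() > r[-1]


def test_annulus_mask_amplitude_independent_of_eccentricity(truth):
    amps = {amplitude_law(c, truth)
            for c in make_condition_grid(4) if c.direction == "rightward"}
    assert len(amps) == 1


def test_directions_antisymmetric(truth):
    for shape, od, idm in (("disk", 21.3, 0.0), ("ring", 60.0, 10.65)):
        r = StimulusCondition(shape, od, idm, 0.36, 30.0, "rightward")
        l = StimulusCondition(shape, od, idm, 0.36, 30.0, "leftward")
        assert amplitude_law(l, truth) == -amplitude_law(r, truth)


@given(scale=st.floats(0.1, 10.0))
@settings(max_examples=20, deadline=None)
def test_amplitude_scaling_is_linear(scale):
    """Doubling (g_e, g_i) or (g_r, r_0) doubles every noiseless amplitude."""
    base = default_truth()
    scaled = BRFTruth(
        dog={sf: DoGParams(p.sigma_e, p.sigma_i, scale * p.g_e, scale * p.g_i)
             for sf, p in base.dog.items()},
        decay={sf: ExpDecayParams(scale * p.g_r, p.tau, scale * p.r_0)
               for sf, p in base.decay.items()},
        noise_sd=0.0, drift_sd=0.0)
    for c in make_condition_grid(1)[:8]:
        assert amplitude_law(c, scaled) == pytest.approx(
            scale * amplitude_law(c, base), rel=1e-12)


def test_trial_determinism(truth):
    cond = StimulusCondition("disk", 21.3, 0.0, 0.36, 30.0, "rightward")
    a = simulate_trial(cond, truth, np.random.default_rng(5))
    b = simulate_trial(cond, truth, np.random.default_rng(5))
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)


def test_noiseless_blank_is_flat(noiseless_truth):
    tr = simulate_trial(None, noiseless_truth, np.random.default_rng(0))
    np.testing.assert_allclose(tr.x, 0.0, atol=1e-15)


def test_noiseless_trial_window_change_equals_amplitude_law(noiseless_truth):
    cond = StimulusCondition("disk", 14.2, 0.0, 0.36, 30.0, "rightward")
    tr = simulate_trial(cond, noiseless_truth, np.random.default_rng(0))
    i0 = int(np.searchsorted(tr.t, 85))
    i1 = int(np.searchsorted(tr.t, 105))
    assert tr.x[i1] - tr.x[i0] == pytest.approx(
        amplitude_law(cond, noiseless_truth), abs=1e-15)
    # flat until latency, 220+ ms epoch on a 1 ms grid
    assert np.all(tr.x[tr.t < noiseless_truth.latency] == 0)
    assert tr.t[-1] >= 220


def test_session_counts_and_order_reproducibility(truth):
    grid = make_condition_grid(1)
    s1 = simulate_session(grid, truth, 3, catch_fraction=0.1, seed=42)
    s2 = simulate_session(grid, truth, 3, catch_fraction=0.1, seed=42)
    assert len(s1.stimulus_trials) == 48 * 3
    assert len(s1.blanks) == round(48 * 3 * 0.1)
    assert [t.condition for t in s1] == [t.condition for t in s2]
    np.testing.assert_array_equal(s1.traces[0].x, s2.traces[0].x)


def test_session_rejects_empty_grid(truth):
    with pytest.raises(ValueError):
        simulate_session([], truth, 1)


def test_noiseless_curve_recovers_amplitude_law(exp1_noiseless_session,
                                                noiseless_truth):
    """build_summation_curve o simulate_session recovers the amplitude law
    exactly, both shapes and directions."""
    for shape in ("disk", "ring"):
        for curve in build_summation_curve(exp1_noiseless_session, shape,
                                           d.REFERENCE_WINDOW):
            for diam, amp in zip(curve.diameters, curve.amp):
                cond = StimulusCondition(
                    shape, 60.0 if shape == "ring" else diam,
                    diam if shape == "ring" else 0.0,
                    curve.sf, curve.speed, curve.direction)
                assert amp == pytest.approx(
                    abs(amplitude_law(cond, noiseless_truth)), abs=1e-12)


def test_fast_amplitude_path_matches_trace_path(truth):
    """The amplitude-level sampler and the full 1 kHz trace path agree on the
    noiseless value and closely on noisy means."""
    grid = [c for c in make_condition_grid(1)
            if c.direction == "rightward" and c.shape == "disk"][:3]
    quiet = BRFTruth(dog=truth.dog, decay=truth.decay, noise_sd=0.0, drift_sd=0.0)
    df = simulate_window_amplitudes(grid, quiet, 2, seed=1)
    for cond in grid:
        got = df[np.isclose(df.outer_diameter, cond.outer_diameter)]["dx"]
        assert got.mean() == pytest.approx(amplitude_law(cond, quiet), abs=1e-12)
    # with noise: means agree within the joint error budget at matched n.
    # Each path carries its own blank-mean offset (a single shared random
    # constant), so the tolerance includes both blank variances as well as
    # the two per-diameter standard errors.
    n, n_catch = 400, 500
    dfn = simulate_window_amplitudes(grid, truth, n, seed=2, n_catch=n_catch)
    sess = simulate_session(grid, truth, n, catch_fraction=1.0, seed=3)
    n_blanks = len(sess.blanks)
    curves = build_summation_curve(sess, "disk", d.REFERENCE_WINDOW)
    c = curves[0]
    dt_s = (d.REFERENCE_WINDOW[1] - d.REFERENCE_WINDOW[0]) * 1e-3
    var_blank = sum(((truth.drift_sd * dt_s) ** 2 + 2 * truth.noise_sd**2) / m
                    for m in (n_catch, n_blanks))
    for diam, amp, se in zip(c.diameters, c.amp, c.se):
        sub = dfn[np.isclose(dfn.outer_diameter, diam)]["dx"]
        fast, se_fast = sub.mean(), sub.std(ddof=1) / np.sqrt(len(sub))
        tol = 6 * np.sqrt(se**2 + se_fast**2 + var_blank)
        assert abs(fast - amp) < tol


def test_session_csv_round_trip(exp1_noiseless_session):
    frame = session_to_frame(exp1_noiseless_session)
    back = frame_to_session(frame)
    assert len(back) == len(exp1_noiseless_session)
    np.testing.assert_allclose(back.traces[5].x, exp1_noiseless_session.traces[5].x)
    assert back.traces[5].condition == exp1_noiseless_session.traces[5].condition
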