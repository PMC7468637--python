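"""Kinematic reduction: smoothing/differentiation, segmentation, measures."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from vdodge.body import Anthropometrics, Posture, forward_kinematics_arrays
from vdodge.errors import DegenerateTrialError, ValidationError
from vdodge.recording import TrialRecording
from vdodge.reduction import (
    aggregate_subject_condition,
    com_displacement,
    detect_movement_bounds,
    filter_trials,
    hand_position_at_contact,
    joint_excursions,
    movement_time,
    savgol_derivative,
)
from vdodge.synth import minimum_jerk_speed_shape


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------

def test_savgol_constant_series():
    y = np.full(101, 3.7)
    sm, d = savgol_derivative(y)
    assert np.allclose(sm, 3.7, atol=1e-12)
    assert np.allclose(d, 0.0, atol=1e-10)


def test_savgol_exact_for_quartic():
    """A degree-4 filter reproduces a global quartic and its derivative
    exactly at interior samples."""
    t = np.arange(120) / 100.0
    y = t**4
    sm, d = savgol_derivative(y, rate=100.0)
    interior = slice(20, -20)
    assert np.allclose(sm[interior], y[interior], atol=1e-9)
    assert np.allclose(d[interior], 4 * t[interior] ** 3, atol=1e-6)


def test_savgol_sine_derivative():
    """On a 1 Hz sine at 100 Hz the filtered derivative tracks the analytic
    cosine; the 41-sample quartic window attenuates the peak by ~0.5%
    (max abs error ~0.032 of an amplitude-2*pi signal), so the comparison
    is bounded accordingly."""
    t = np.arange(300) / 100.0
    _, d = savgol_derivative(np.sin(2 * np.pi * t), rate=100.0)
    expected = 2 * np.pi * np.cos(2 * np.pi * t)
    err = np.max(np.abs(d[20:-20] - expected[20:-20]))
    assert err < 0.04
    # relative to the derivative amplitude the distortion stays below 1%
    assert err / (2 * np.pi) < 0.01


def test_savgol_matches_bruteforce_windows(rng):
    """Filter output equals an explicit per-window least-squares quartic
    fit (value and derivative at the window center) on random series."""
    for _ in range(10):
        y = rng.normal(size=90).cumsum()
        sm, d = savgol_derivative(y, rate=100.0)
        x = np.arange(-20, 21)
        for c in range(20, 70):
            coef = np.polynomial.polynomial.polyfit(x, y[c - 20 : c + 21], 4)
            assert abs(sm[c] - coef[0]) < 1e-9
            assert abs(d[c] - coef[1] * 100.0) < 1e-7


def test_savgol_validation():
    with pytest.raises(ValidationError):
        savgol_derivative(np.zeros(40))  # shorter than window
    with pytest.raises(ValidationError):
        savgol_derivative(np.zeros(100), window=40)  # even window
    with pytest.raises(ValidationError):
        savgol_derivative(np.zeros(100), window=5, order=5)


def test_savgol_nan_propagates():
    y = np.ones(100)
    y[50] = np.nan
    sm, _ = savgol_derivative(y)
    assert np.isnan(sm[50])


# ---------------------------------------------------------------------------
# movement bounds
# ---------------------------------------------------------------------------

def test_bounds_on_analytic_minimum_jerk():
    """Detected bounds on a densely sampled minimum-jerk speed profile sit
    within one sample of the analytic 5%-of-peak crossings."""
    T = 0.8
    t = np.arange(0, int(T * 100) + 1) / 100.0
    speed = minimum_jerk_speed_shape(t / T)
    b = detect_movement_bounds(speed)
    peak = minimum_jerk_speed_shape(0.5)
    f = lambda x: minimum_jerk_speed_shape(x) - 0.05 * peak
    lo = brentq(f, 1e-9, 0.5) * T
    hi = brentq(f, 0.5, 1 - 1e-9) * T
    assert abs(t[b.onset_index] - lo) <= 0.01 + 1e-12
    assert abs(t[b.contact_index] - hi) <= 0.01 + 1e-12
    assert b.onset_index <= b.peak_index <= b.contact_index


def test_bounds_single_spike_degenerate():
    speed = np.zeros(50)
    speed[25] = 1.0
    b = detect_movement_bounds(speed)
    assert b.onset_index == b.peak_index - 1 or b.onset_index <= b.peak_index
    assert speed[b.onset_index] <= 0.05 * b.peak_speed
    assert speed[b.contact_index] <= 0.05 * b.peak_speed


def test_bounds_truncation_flags():
    speed = np.full(60, 0.5)
    speed[30] = 1.0  # tails never fall to 5% of peak
    b = detect_movement_bounds(speed)
    assert b.truncated_start and b.truncated_end
    assert b.onset_index == 0 and b.contact_index == 59


def test_bounds_scale_invariance(rng):
    speed = np.abs(np.convolve(rng.normal(size=200), np.ones(20) / 20, mode="same"))
    b1 = detect_movement_bounds(speed)
    b2 = detect_movement_bounds(37.5 * speed)
    assert (b1.onset_index, b1.peak_index, b1.contact_index) == (
        b2.onset_index, b2.peak_index, b2.contact_index
    )


def test_bounds_all_zero_raises():
    with pytest.raises(DegenerateTrialError):
        detect_movement_bounds(np.zeros(100))


def test_movement_time_arithmetic():
    from vdodge.reduction import MovementBounds

    b = MovementBounds(onset_index=10, peak_index=40, contact_index=75, peak_speed=1.0)
    assert movement_time(b, 100.0) == 650.0
    b0 = MovementBounds(onset_index=5, peak_index=5, contact_index=5, peak_speed=1.0)
    assert movement_time(b0, 100.0) == 0.0


# ---------------------------------------------------------------------------
# trial measures on constructed recordings
# ---------------------------------------------------------------------------

def _static_recording(posture=None, n=120):
    anthro = Anthropometrics(hip_height=0.9, trunk_length=0.5, arm_length=0.7)
    posture = posture or Posture(shoulder=60.0, elbow=20.0)
    angles = {j: np.full(n, getattr(posture, j)) for j in Posture.JOINTS}
    angles["arm_azimuth"] = np.zeros(n)
    lm = forward_kinematics_arrays(angles, anthro)
    return TrialRecording(time=np.arange(n) / 100.0, angles=angles, landmarks=lm, meta={})


def _lean_recording(spine_from=0.0, spine_to=30.0, n=160):
    """Smooth pure-trunk-lean recording (quintic ramp)."""
    anthro = Anthropometrics(hip_height=0.9, trunk_length=0.5, arm_length=0.7)
    tau = np.clip((np.arange(n) - 30) / (n - 60), 0, 1)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    angles = {j: np.zeros(n) for j in Posture.JOINTS}
    angles["shoulder"] = np.full(n, 90.0)
    angles["spine"] = spine_from + (spine_to - spine_from) * s
    angles["arm_azimuth"] = np.zeros(n)
    lm = forward_kinematics_arrays(angles, anthro)
    return TrialRecording(time=np.arange(n) / 100.0, angles=angles, landmarks=lm, meta={})


def test_static_recording_zero_measures():
    rec = _static_recording()
    from vdodge.reduction import MovementBounds

    b = MovementBounds(onset_index=10, peak_index=50, contact_index=100, peak_speed=1.0)
    exc = joint_excursions(rec, b)
    assert all(v == 0.0 for v in exc.values())
    assert np.allclose(com_displacement(rec, b), 0.0, atol=1e-12)


def test_forward_lean_signs():
    """A pure forward trunk lean moves the COM forward and down, with no
    mediolateral component, and gives a positive spine excursion."""
    rec = _lean_recording()
    from vdodge.reduction import detect_movement_bounds, savgol_derivative

    _, vel = savgol_derivative(rec.hand_centroid())
    b = detect_movement_bounds(np.linalg.norm(vel, axis=1))
    com = com_displacement(rec, b)
    assert com[0] > 0.5  # forward (cm)
    assert com[2] < -0.5  # downward
    assert abs(com[1]) < 1e-9
    exc = joint_excursions(rec, b)
    assert exc["spine"] > 25.0


def test_hand_position_geometry():
    rec = _static_recording(Posture())  # arm hanging: hand above ankle midpoint
    from vdodge.reduction import MovementBounds

    b = MovementBounds(onset_index=0, peak_index=1, contact_index=2, peak_speed=1.0)
    hand = hand_position_at_contact(rec, b)
    assert abs(hand[0]) < 1e-9 and abs(hand[1]) < 1e-9
    assert np.isclose(hand[2], (0.9 + 0.5 - 0.7) * 100, atol=1e-9)


def test_missing_channels_raise():
    rec = _static_recording()
    from vdodge.reduction import MovementBounds

    b = MovementBounds(onset_index=0, peak_index=1, contact_index=2, peak_speed=1.0)
    del rec.angles["spine"]
    with pytest.raises(ValidationError):
        joint_excursions(rec, b)
    del rec.landmarks["hand_l"]
    with pytest.raises(ValidationError):
        hand_position_at_contact(rec, b)


# ---------------------------------------------------------------------------
# filtering and aggregation
# ---------------------------------------------------------------------------

def _measure_frame(rows):
    return pd.DataFrame(rows)


def test_filter_keeps_standard_ball_blocks():
    df = _measure_frame(
        [
            dict(kind="block", diameter=0.24, movement_time_ms=600.0),
            dict(kind="block", diameter=0.18, movement_time_ms=600.0),
            dict(kind="duck", diameter=0.24, movement_time_ms=600.0),
            dict(kind="block", diameter=0.24, movement_time_ms=650.0),
        ]
    )
    kept = filter_trials(df)
    assert len(kept) == 2
    assert set(kept["diameter"]) == {0.24}
    assert set(kept["kind"]) == {"block"}


def test_filter_duck_only_empty():
    df = _measure_frame([dict(kind="duck", diameter=0.24)])
    assert filter_trials(df).empty
    assert filter_trials(pd.DataFrame()).empty


def test_aggregate_means_and_invariance(rng):
    rows = []
    for d, v in (("left", 10.0), ("center", 20.0), ("right", 30.0)):
        rows.append(
            dict(subject_id="S1", sex="female", perspective="first", impact_height="IH1",
                 direction=d, movement_time_ms=v, success=True)
        )
    df = _measure_frame(rows)
    agg = aggregate_subject_condition(df)
    assert len(agg) == 1
    assert agg["movement_time_ms"].iloc[0] == 20.0
    assert agg["n_trials"].iloc[0] == 3
    assert agg["success_rate"].iloc[0] == 1.0
    shuffled = df.sample(frac=1.0, random_state=1)
    agg2 = aggregate_subject_condition(shuffled)
    pd.testing.assert_frame_equal(
        agg.sort_index(axis=1), agg2.sort_index(axis=1), check_like=True
    )


def test_aggregate_direction_balanced():
    """Repeated launches to one direction do not re-weight the cell mean."""
    rows = [
        dict(subject_id="S1", sex="female", perspective="first", impact_height="IH1",
             direction="left", movement_time_ms=10.0),
        dict(subject_id="S1", sex="female", perspective="first", impact_height="IH1",
             direction="left", movement_time_ms=10.0),
        dict(subject_id="S1", sex="female", perspective="first", impact_height="IH1",
             direction="center", movement_time_ms=40.0),
    ]
    agg = aggregate_subject_condition(_measure_frame(rows))
    assert agg["movement_time_ms"].iloc[0] == 25.0  # (10 + 40)/2, not 20

    with pytest.raises(ValidationError):
        aggregate_subject_condition(pd.DataFrame())
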