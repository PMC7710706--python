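"""Swing peaks, step segmentation/averaging, and step metrics."""

import numpy as np
import pytest

from backstep.kinematics import (
    STEP_WINDOW_PRESETS,
    StepWindowSpec,
    SwingPeakSet,
    average_steps,
    detect_peaks_in_trace,
    detect_swing_peaks,
    flexion_slope,
    joint_angle_range,
    max_flexion,
    min_step_angle,
    segment_steps,
    step_frequency,
    step_geometry,
)

LONG = STEP_WINDOW_PRESETS["long"]


# ---------------------------------------------------------------------------
# swing-peak detection


def test_sine_peak_count():
    fps, f, dur = 200.0, 3.0, 5.0
    t = np.arange(int(dur * fps)) / fps
    peaks = detect_peaks_in_trace(np.sin(2 * np.pi * f * t), fps)
    assert abs(len(peaks) - dur * f) <= 1


def test_constant_trace_has_no_peaks():
    assert len(detect_peaks_in_trace(np.ones(500), 200.0)) == 0


def test_all_nan_trace_rejected():
    with pytest.raises(ValueError):
        detect_peaks_in_trace(np.full(500, np.nan), 200.0)


def test_peaks_fall_inside_true_swing_bouts(tripod_dataset):
    ds = tripod_dataset
    for leg in ds.true_swing_mask.legs:
        peaks = detect_swing_peaks(ds.pose, leg)
        truth = ds.true_swing_mask.leg(leg)
        assert len(peaks) > 0
        assert truth[peaks.frames].all()  # never in stance
        # exactly one peak per fully recorded swing bout
        edges = np.flatnonzero(np.diff(np.r_[False, truth, False]))
        n_in_bout = [
            np.sum((peaks.frames >= s) & (peaks.frames < e))
            for s, e in zip(edges[::2], edges[1::2])
        ]
        assert all(n == 1 for n in n_in_bout)


# ---------------------------------------------------------------------------
# step segmentation


def _ens(peaks, n=2000, spec=LONG, **kw):
    trace = np.arange(n, dtype=float)
    return segment_steps({"t": trace}, SwingPeakSet(np.array(peaks), 200.0), spec, **kw)


def test_isolated_peak_window_span():
    ens = _ens([1000])
    assert ens.n_steps == 1
    vals = ens.traces["t"][0]
    assert np.nanmin(vals) == 960 and np.nanmax(vals) == 1259
    assert np.isfinite(vals).all()
    assert vals[LONG.peak_index] == 1000


def test_truncation_before_next_peak():
    ens = _ens([1000, 1100])
    first = ens.traces["t"][0]
    valid = np.isfinite(first)
    # truncated 8 frames before the next peak: last kept frame is peak + 91
    assert np.nanmax(first) == 1091
    assert valid[: LONG.peak_index + 92].all() and not valid[LONG.peak_index + 92 :].any()
    np.testing.assert_array_equal(ens.valid[0], [0, LONG.peak_index + 92])


def test_left_clipped_step_records_offset():
    ens = _ens([10])
    assert ens.valid[0, 0] == LONG.peak_index - 10
    assert ens.peak_offsets[0] == 10
    assert np.nanmin(ens.traces["t"][0]) == 0


def test_steps_outside_analysis_window_dropped():
    ens = _ens([100, 1000, 1900], analysis_window=(500, 1500))
    assert ens.n_steps == 1 and ens.n_dropped == 2
    assert ens.peak_frames.tolist() == [1000]


def test_post_peak_regions_never_overlap(rng):
    """Brute-force check of the no-overlap invariant on random peak trains."""
    for _ in range(20):
        peaks = np.unique(rng.integers(300, 1700, size=8))
        ens = _ens(peaks.tolist())
        claimed = np.zeros(2000, bool)
        for i in range(ens.n_steps):
            p = ens.peak_frames[i]
            v0, v1 = ens.valid[i]
            start = p - LONG.peak_index
            post = np.arange(max(start + v0, p), start + v1)
            assert not claimed[post].any()
            claimed[post] = True


# ---------------------------------------------------------------------------
# step averaging


def test_average_of_identical_steps_is_member():
    ens = _ens([500, 1000, 1500])  # far apart: no truncation
    avg = average_steps(ens)
    member = ens.traces["t"][1] - 1000  # remove the offset
    np.testing.assert_allclose(avg.traces["t"] - avg.traces["t"][LONG.peak_index], member)
    assert (avg.counts == 3).all()


def test_truncated_tail_excluded_from_denominator():
    ens = _ens([1000, 1150])
    avg = average_steps(ens)
    first, second = ens.traces["t"]
    cut = int(ens.valid[0, 1])
    # beyond the first step's truncation the average equals the second step alone
    np.testing.assert_array_equal(avg.traces["t"][cut:], second[cut:])
    assert (avg.counts[cut:] == 1).all()


def test_inferred_swing_interval_matches_truth(tripod_dataset):
    ds = tripod_dataset
    leg = "LH"
    peaks = detect_swing_peaks(ds.pose, leg)
    tip_y = ds.pose.xy(f"{leg}_tarsal_tip")[:, 1]
    spec = STEP_WINDOW_PRESETS["short"]
    ens = segment_steps({"tip_y": tip_y}, peaks, spec)
    avg = average_steps(ens, height_trace="tip_y")
    assert avg.swing_interval is not None
    lo, hi = avg.swing_interval
    # true swing within the window, centered on the aligned peak
    half = int(round(0.5 * (1 - ds.params.duty_factor) * 200.0 / ds.params.step_frequency_hz))
    t0, t1 = spec.peak_index - half, spec.peak_index + half
    inter = max(0, min(hi, t1) - max(lo, t0))
    union = max(hi, t1) - min(lo, t0)
    assert inter / union >= 0.8


# ---------------------------------------------------------------------------
# step geometry


def test_step_size_three_four_five():
    traj = np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]])
    geom = step_geometry(traj)
    assert geom.step_size == pytest.approx(5.0)


def test_amplitude_above_segment():
    geom = step_geometry(np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]]))
    assert geom.swing_stroke_amplitude == pytest.approx(1.0)


def test_distance_beyond_segment_extent_uses_endpoint():
    """A dorsal point past the segment's x-extent measures to the endpoint."""
    from backstep.kinematics import point_to_segment_distance

    p = np.array([3.0, 1.0])
    a, b = np.array([0.0, 0.0]), np.array([2.0, 0.0])
    d = point_to_segment_distance(p, a, b)
    assert d == pytest.approx(np.sqrt(2.0))
    # brute-force min over densely sampled segment points
    t = np.linspace(0.0, 1.0, 10_000)[:, None]
    brute = np.min(np.linalg.norm(a * (1 - t) + b * t - p, axis=1))
    assert abs(d - brute) < 1e-6


def test_amplitude_matches_dense_sampling_oracle(rng):
    for _ in range(50):
        traj = rng.normal(size=(40, 2))
        geom = step_geometry(traj)
        t = np.linspace(0.0, 1.0, 10_000)[:, None]
        seg = geom.aep * (1 - t) + geom.pep * t
        brute = np.min(np.linalg.norm(seg - geom.dep, axis=1))
        assert abs(geom.swing_stroke_amplitude - brute) < 1e-6


def test_geometry_time_reversal_invariant(rng):
    traj = rng.normal(size=(30, 2))
    a, b = step_geometry(traj), step_geometry(traj[::-1])
    assert a.step_size == b.step_size
    assert a.swing_stroke_amplitude == pytest.approx(b.swing_stroke_amplitude)


def test_degenerate_trajectory_flagged():
    geom = step_geometry(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]]))
    assert not geom.well_defined
    assert np.isnan(geom.swing_stroke_amplitude)


# ---------------------------------------------------------------------------
# scalar metrics


def test_step_frequency_examples():
    fps = 100.0
    assert step_frequency(SwingPeakSet(np.array([0, 100, 200, 300]), fps)) == pytest.approx(1.0)
    assert step_frequency(SwingPeakSet(np.array([0, 40, 100]), fps)) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        step_frequency(SwingPeakSet(np.array([5]), fps))


def test_step_frequency_recovers_generator_rate(tripod_dataset):
    from backstep.synth import GaitParams, simulate_gait

    ds = simulate_gait(GaitParams(step_frequency_hz=2.5), duration_s=10.0, fps=200.0)
    peaks = detect_swing_peaks(ds.pose, "LF")
    assert step_frequency(peaks) == pytest.approx(2.5, abs=0.1)


def test_joint_angle_range():
    assert joint_angle_range(np.array([60.0, 90.0, np.nan, 150.0])) == pytest.approx(90.0)


def test_max_flexion_monotone_decrease():
    fps = 100.0
    trace = np.linspace(120.0, 60.0, 100)
    assert max_flexion(trace, fps, onset_s=0.0) == pytest.approx(60.0)


def test_max_flexion_stops_at_reextension():
    fps = 100.0
    t = np.arange(100) / fps
    trace = np.full(100, 120.0)
    trace[20:40] = np.linspace(120, 80, 20)  # dip to 80 at 0.3-0.4 s
    trace[40:60] = np.linspace(80, 110, 20)  # re-extension > 5 deg
    trace[60:95] = np.linspace(110, 50, 35)  # deeper later dip
    assert max_flexion(trace, fps, onset_s=0.0) == pytest.approx(80.0)
    del t


def test_max_flexion_flat_trace():
    assert max_flexion(np.full(200, 95.0), 100.0, onset_s=0.5) == pytest.approx(95.0)


def test_min_step_angle():
    trace = np.r_[np.linspace(120, 45, 30), np.linspace(45, 130, 30)]
    assert min_step_angle(trace, peak_index=50) == pytest.approx(45.0)
    rising = np.linspace(60.0, 120.0, 50)
    assert min_step_angle(rising, peak_index=40) == pytest.approx(60.0)
    with pytest.warns(UserWarning):
        assert np.isnan(min_step_angle(rising, peak_index=0))


def test_flexion_slope_recovers_line():
    fps = 200.0
    t = np.arange(260) / fps
    trace = np.r_[np.linspace(100.0, 138.0, 40), 140.0 - 100.0 * t]
    assert flexion_slope(trace, fps) == pytest.approx(-100.0, abs=1e-9)
    assert flexion_slope(np.full(300, 90.0), fps) == pytest.approx(0.0)


def test_flexion_slope_noisy_line(rng):
    fps = 200.0
    slope_true = -120.0
    t = np.arange(260) / fps
    errors = []
    for _ in range(20):
        trace = 140.0 + slope_true * t + rng.normal(0, 2.0, 260)
        errors.append(flexion_slope(trace, fps) - slope_true)
    assert np.max(np.abs(errors)) < 3.0


def test_window_spec_validation():
    with pytest.raises(ValueError):
        StepWindowSpec(100, 100)
    with pytest.raises(ValueError):
        StepWindowSpec(100, 10, -1)
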