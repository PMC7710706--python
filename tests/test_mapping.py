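"""Session handling, ΔF/F, cross-covariance, and response-map assembly."""

import numpy as np
import pytest

from backstep.mapping import (
    ResponseKernel,
    SampleRecording,
    StimulusProtocol,
    build_kernel,
    concat_sessions,
    protocol_summary,
    response_maps,
    rigid_motion_correct,
    roi_dff,
    split_hyperstack,
    voxel_crosscov,
)


def _recording(n_sessions=10, shape=(2, 4, 5), nvol=60, fill=100.0):
    protocol = StimulusProtocol(session_volumes=nvol)
    sessions = [np.full((nvol,) + shape, fill) for _ in range(n_sessions)]
    return SampleRecording(sessions, protocol)


# ---------------------------------------------------------------------------
# sessions


def test_concat_ten_sessions_gives_600_volumes():
    hs = concat_sessions(_recording())
    assert hs.shape[0] == 600


def test_single_session_concat_is_identity():
    rec = _recording(n_sessions=1)
    np.testing.assert_array_equal(concat_sessions(rec), rec.sessions[0])


def test_concat_split_round_trip(rng):
    protocol = StimulusProtocol(session_volumes=60)
    sessions = [rng.normal(size=(60, 2, 3, 4)) for _ in range(4)]
    rec = SampleRecording(sessions, protocol)
    back = split_hyperstack(concat_sessions(rec), 60)
    for a, b in zip(back, sessions):
        np.testing.assert_array_equal(a, b)


def test_session_shape_mismatch_rejected():
    protocol = StimulusProtocol()
    with pytest.raises(ValueError):
        SampleRecording(
            [np.zeros((60, 2, 3, 4)), np.zeros((60, 2, 3, 5))], protocol
        )


# ---------------------------------------------------------------------------
# cross-covariance


def test_maxlag_five_gives_eleven_values(rng):
    hs = rng.normal(size=(600, 2, 3, 4))
    kernel = ResponseKernel(rng.normal(size=60))
    field = voxel_crosscov(hs, kernel, maxlag=5)
    assert field.values.shape == (2, 3, 4, 11)
    np.testing.assert_array_equal(field.lags, np.arange(-5, 6))


def test_constant_voxel_gives_zero_vector(rng):
    hs = np.full((120, 1, 1, 1), 7.0)
    kernel = ResponseKernel(rng.normal(size=60))
    field = voxel_crosscov(hs, kernel, maxlag=5)
    np.testing.assert_allclose(field.values, 0.0, atol=1e-12)


@pytest.mark.parametrize("maxlag", [1, 3, 5])
def test_crosscov_matches_brute_force(rng, maxlag):
    """Double-loop oracle over lag and time, zero padding outside overlap."""
    n, klen = 120, 60
    kernel = ResponseKernel(rng.normal(size=klen))
    k = np.tile(kernel.trace, n // klen)
    kd = k - k.mean()
    for _ in range(25):
        x = rng.normal(size=n)
        xd = x - x.mean()
        brute = [
            sum(xd[t + tau] * kd[t] for t in range(n) if 0 <= t + tau < n)
            for tau in range(-maxlag, maxlag + 1)
        ]
        got = voxel_crosscov(x.reshape(n, 1, 1, 1), kernel, maxlag).values[0, 0, 0]
        np.testing.assert_allclose(got, brute, atol=1e-10)


def test_crosscov_linear_in_series(rng):
    x = rng.normal(size=(120, 1, 1, 1))
    kernel = ResponseKernel(rng.normal(size=60))
    a = voxel_crosscov(x, kernel, 5).values
    b = voxel_crosscov(3.5 * x, kernel, 5).values
    np.testing.assert_allclose(b, 3.5 * a, rtol=1e-12)


def test_biased_normalization_scales_only(rng):
    x = rng.normal(size=(120, 1, 1, 1))
    kernel = ResponseKernel(rng.normal(size=60))
    a = voxel_crosscov(x, kernel, 5, normalization="none").values
    b = voxel_crosscov(x, kernel, 5, normalization="biased").values
    np.testing.assert_allclose(b, a / 120.0, rtol=1e-12)


def test_length_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        voxel_crosscov(rng.normal(size=(100, 1, 1, 1)), ResponseKernel(np.ones(60)), 5)


# ---------------------------------------------------------------------------
# response maps


def test_all_negative_vector():
    from backstep.mapping import VoxelCovField

    vals = -np.abs(np.random.default_rng(0).normal(size=(1, 1, 1, 11))) - 0.1
    maps = response_maps(VoxelCovField(vals, 5))
    assert maps.activated[0, 0, 0] == 0.0
    assert maps.inhibited[0, 0, 0] == vals.min()


def test_kernel_voxel_closed_form(rng):
    """A voxel equal to the tiled kernel peaks at lag 0 with value sum((k-kbar)^2)."""
    kernel = ResponseKernel(rng.normal(size=60))
    k = np.tile(kernel.trace, 2)
    field = voxel_crosscov(k.reshape(-1, 1, 1, 1), kernel, 5)
    kd = k - k.mean()
    maps = response_maps(field)
    assert field.values[0, 0, 0, 5] == pytest.approx(np.sum(kd**2))
    assert maps.activated[0, 0, 0] == pytest.approx(np.sum(kd**2))
    assert maps.inhibited[0, 0, 0] <= 0.0


def test_negation_swaps_maps(rng):
    x = rng.normal(size=(120, 2, 2, 2))
    kernel = ResponseKernel(rng.normal(size=60))
    m_pos = response_maps(voxel_crosscov(x, kernel, 5))
    m_neg = response_maps(voxel_crosscov(-x, kernel, 5))
    np.testing.assert_allclose(m_neg.activated, -m_pos.inhibited, atol=1e-10)
    np.testing.assert_allclose(m_neg.inhibited, -m_pos.activated, atol=1e-10)


# ---------------------------------------------------------------------------
# ΔF/F and kernels


def test_constant_recording_dff_zero():
    rec = _recording()
    roi = np.zeros(rec.grid_shape, bool)
    roi[0, :2, :2] = True
    dff = roi_dff(rec, roi)
    np.testing.assert_allclose(dff.averaged, 0.0, atol=1e-12)
    np.testing.assert_allclose(dff.f0, 100.0)


def test_step_doubling_gives_dff_one():
    protocol = StimulusProtocol(session_volumes=60)
    sess = np.full((60, 1, 2, 2), 50.0)
    sess[20:] = 100.0  # doubles after the baseline frames (2-9)
    rec = SampleRecording([sess], protocol)
    roi = np.ones((1, 2, 2), bool)
    dff = roi_dff(rec, roi)
    np.testing.assert_allclose(dff.averaged[20:], 1.0)
    np.testing.assert_allclose(dff.averaged[:8], 0.0)


def test_dff_gain_invariant(rng):
    protocol = StimulusProtocol(session_volumes=60)
    base = rng.uniform(50, 150, size=(60, 2, 2, 2))
    roi = np.ones((2, 2, 2), bool)
    a = roi_dff(SampleRecording([base], protocol), roi).averaged
    b = roi_dff(SampleRecording([base * 7.3], protocol), roi).averaged
    np.testing.assert_allclose(a, b, rtol=1e-10)


def test_build_kernel_single_and_cancelling():
    k = np.sin(np.linspace(0, 3, 60))
    assert np.array_equal(build_kernel([k]).trace, k)
    np.testing.assert_allclose(build_kernel([k, -k]).trace, 0.0, atol=1e-15)
    with pytest.raises(ValueError):
        build_kernel([k, k[:30]])


# ---------------------------------------------------------------------------
# motion correction


def test_unshifted_stack_gets_zero_shifts(rng):
    stack = rng.normal(100, 5, size=(3, 2, 16, 16))
    stack[1:] = stack[0]
    corrected, shifts = rigid_motion_correct(stack, reference=0)
    np.testing.assert_array_equal(shifts, 0)
    np.testing.assert_allclose(corrected, stack)


def test_injected_shift_recovered(rng):
    stack = np.tile(rng.normal(100, 5, size=(1, 1, 32, 32)), (4, 1, 1, 1))
    stack[2, 0] = np.roll(stack[0, 0], (3, -2), axis=(0, 1))
    _, shifts = rigid_motion_correct(stack, reference=0)
    np.testing.assert_array_equal(shifts[2, 0], [-3, 2])


def test_none_mode_is_identity(rng):
    stack = rng.normal(size=(3, 2, 8, 8))
    corrected, shifts = rigid_motion_correct(stack, mode="none")
    np.testing.assert_array_equal(corrected, stack)
    assert not shifts.any()


# ---------------------------------------------------------------------------
# protocol arithmetic


def test_duty_cycle_from_pulse_train():
    assert protocol_summary(StimulusProtocol())["duty_cycle"] == pytest.approx(0.25)
    zero = StimulusProtocol(pulse_width_s=0.0)
    assert protocol_summary(zero)["duty_cycle"] == 0.0


def test_light_intensity_from_fov():
    s = protocol_summary(StimulusProtocol())
    assert s["mean_intensity_mw_mm2"] == pytest.approx(1.27, abs=0.01)


def test_protocol_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(epochs=((50.0, 20.0),))  # runs past the session
    with pytest.raises(ValueError):
        StimulusProtocol(pulse_width_s=0.03, pulse_rate_hz=50.0)
    with pytest.raises(ValueError):
        protocol_summary(
            StimulusProtocol(fov_diameter_mm=0.0)
        )
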