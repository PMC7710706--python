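"""Step-cycle kinematics from pose tables.

The chain implemented here mirrors a standard tethered-walking analysis:
joint angles from tracked landmarks, swing peaks from z-scored tarsal-tip
height, swing-peak-aligned step windows with truncation at neighbouring
peaks, step averaging with an inferred swing interval, and the per-step
geometry/angle metrics (step size, swing-stroke amplitude, angle range,
maximal flexion, pre-peak minimum angle, flexion slope, step frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

from .bodyplan import BODY_AXIS_LANDMARKS, JOINT_NAMES, angles_from_landmarks
from .pose import PoseSeries

__all__ = [
    "JointAngleSeries",
    "SwingPeakSet",
    "StepWindowSpec",
    "StepEnsemble",
    "StepAverage",
    "StepGeometry",
    "STEP_WINDOW_PRESETS",
    "compute_joint_angles",
    "detect_swing_peaks",
    "detect_peaks_in_trace",
    "segment_steps",
    "average_steps",
    "step_geometry",
    "step_frequency",
    "joint_angle_range",
    "max_flexion",
    "min_step_angle",
    "flexion_slope",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class JointAngleSeries:
    """Per-joint interior angle traces in degrees, NaN where undefined."""

    fps: float
    angles: np.ndarray  # (n_frames, 4)
    joint_names: tuple[str, ...] = JOINT_NAMES

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        if self.angles.ndim != 2 or self.angles.shape[1] != len(self.joint_names):
            raise ValueError("angles must have shape (n_frames, n_joints)")

    def trace(self, joint: str) -> np.ndarray:
        return self.angles[:, self.joint_names.index(joint)]


@dataclass
class SwingPeakSet:
    """Ordered swing-peak frame indices for one leg."""

    frames: np.ndarray
    fps: float
    prominence_z: float | None = None
    min_separation_s: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("peak frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames / self.fps


@dataclass(frozen=True)
class StepWindowSpec:
    """Swing-peak-aligned analysis window.

    ``window_frames`` is the window length, ``peak_index`` the position of the
    swing peak inside it, and ``margin_frames`` the number of frames kept clear
    of a neighbouring swing peak when a step is truncated.
    """

    window_frames: int
    peak_index: int
    margin_frames: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.peak_index < self.window_frames:
            raise ValueError("peak_index must lie inside the window")
        if self.margin_frames < 0:
            raise ValueError("margin_frames must be non-negative")


#: 0.5-s window at 200 fps: peak preceded by 49 and followed by 50 frames.
#: 1.5-s window at 200 fps: peak at frame 40 (200 ms shown before the peak).
STEP_WINDOW_PRESETS: dict[str, StepWindowSpec] = {
    "short": StepWindowSpec(100, 49, 8),
    "long": StepWindowSpec(300, 40, 8),
}


@dataclass
class StepEnsemble:
    """Swing-peak-aligned step windows, NaN-padded where truncated.

    Every trace array has shape (n_steps, window_frames, ...); frames outside
    a step's ``valid`` half-open range are NaN, never zero-filled.
    """

    spec: StepWindowSpec
    fps: float
    peak_frames: np.ndarray  # (n_steps,) source frame of each swing peak
    valid: np.ndarray  # (n_steps, 2) valid [start, end) within the window
    traces: dict[str, np.ndarray]
    n_dropped: int = 0
    source_id: str | None = None

    @property
    def n_steps(self) -> int:
        return len(self.peak_frames)

    @property
    def peak_offsets(self) -> np.ndarray:
        """Frames from each step's (possibly clipped) start to its swing peak."""
        return self.spec.peak_index - self.valid[:, 0]


@dataclass
class StepAverage:
    """Pointwise average over an ensemble plus the inferred swing interval."""

    traces: dict[str, np.ndarray]
    counts: np.ndarray  # steps contributing at each window index
    swing_interval: tuple[int, int] | None  # half-open frame range, or None


@dataclass
class StepGeometry:
    """Extreme positions and derived geometry of one step's tip trajectory."""

    aep: np.ndarray
    pep: np.ndarray
    dep: np.ndarray
    step_size: float
    swing_stroke_amplitude: float
    well_defined: bool = True


# ---------------------------------------------------------------------------
# operations


def compute_joint_angles(
    pose: PoseSeries,
    leg: str,
    confidence_threshold: float = 0.9,
    body_axis: tuple[str, str] = BODY_AXIS_LANDMARKS,
) -> JointAngleSeries:
    """Interior joint angles of one leg, NaN-masked by landmark confidence.

    The body-coxa angle is measured against the body axis through the two
    midline landmarks (anterior minus posterior); if those are missing the
    anterior +x direction of the analysis frame is used.  Frames where any
    defining landmark falls below ``confidence_threshold`` are NaN.
    """
    points = pose.leg_points(leg)
    conf = pose.leg_conf(leg)

    names = set(pose.landmark_names)
    axis_conf = None
    if all(n in names for n in body_axis):
        anterior = pose.xy(body_axis[0]) - pose.xy(body_axis[1])
        axis_conf = np.minimum(pose.conf(body_axis[0]), pose.conf(body_axis[1]))
    else:
        anterior = np.array([1.0, 0.0])

    angles = angles_from_landmarks(points, body_axis_anterior=anterior)

    n_bad = int(np.sum(~np.isfinite(angles)))
    if n_bad:
        warnings.warn(
            f"{leg}: {n_bad} joint-angle values undefined (coincident landmarks)",
            stacklevel=2,
        )

    # Joint j is defined by leg landmarks j-1..j+1 (body axis for joint 0).
    for j in range(4):
        lo = max(j - 1, 0)
        bad = np.min(conf[:, lo : j + 2], axis=1) < confidence_threshold
        if j == 0 and axis_conf is not None:
            bad |= axis_conf < confidence_threshold
        angles[bad, j] = np.nan
    return JointAngleSeries(fps=pose.fps, angles=angles)


def detect_peaks_in_trace(
    height: np.ndarray,
    fps: float,
    prominence_z: float = 1.0,
    min_separation_s: float = 0.05,
) -> SwingPeakSet:
    """Swing peaks as prominent local maxima of a z-scored height trace."""
    height = np.asarray(height, float)
    finite = np.isfinite(height)
    if not finite.any():
        raise ValueError("cannot detect peaks in an all-NaN trace")
    mu = np.nanmean(height)
    sd = np.nanstd(height)
    if sd == 0:
        return SwingPeakSet(
            np.empty(0, int), fps, prominence_z, min_separation_s
        )
    z = (height - mu) / sd
    # find_peaks does not accept NaN; fill with the minimum so gaps never peak.
    z_filled = np.where(finite, z, np.nanmin(z))
    distance = max(int(round(min_separation_s * fps)), 1)
    peaks, _ = signal.find_peaks(z_filled, prominence=prominence_z, distance=distance)
    peaks = peaks[finite[peaks]]
    return SwingPeakSet(peaks, fps, prominence_z, min_separation_s)


def detect_swing_peaks(
    pose: PoseSeries,
    leg: str,
    prominence_z: float = 1.0,
    min_separation_s: float = 0.05,
) -> SwingPeakSet:
    """Swing peaks of one leg from its z-scored tarsal-tip height."""
    if pose.duration_s < 1.0:
        raise ValueError("need at least 1 s of data for swing-peak detection")
    tip_y = pose.xy(f"{leg}_tarsal_tip")[:, 1]
    return detect_peaks_in_trace(tip_y, pose.fps, prominence_z, min_separation_s)


def segment_steps(
    series: Mapping[str, np.ndarray],
    peaks: SwingPeakSet,
    spec: StepWindowSpec,
    analysis_window: tuple[int, int] | None = None,
) -> StepEnsemble:
    """Cut swing-peak-aligned step windows out of frame-indexed traces.

    Each peak yields one step spanning ``[peak - peak_index, peak - peak_index
    + window_frames)``.  Steps are clipped at the analysis-window boundaries
    and truncated ``margin_frames`` clear of a neighbouring swing peak that
    falls inside the window.  Steps left empty by clipping are dropped and
    counted in ``n_dropped``.
    """
    arrays = {k: np.asarray(v, float) for k, v in series.items()}
    if not arrays:
        raise ValueError("no traces supplied")
    n_frames = {v.shape[0] for v in arrays.values()}
    if len(n_frames) != 1:
        raise ValueError("all traces must share the frame axis length")
    n = n_frames.pop()
    if peaks.frames.size and (peaks.frames.min() < 0 or peaks.frames.max() >= n):
        raise ValueError("peaks outside the series bounds")

    win_lo, win_hi = (0, n) if analysis_window is None else analysis_window
    win_lo, win_hi = max(win_lo, 0), min(win_hi, n)

    kept, valid = [], []
    pk = peaks.frames
    for i, p in enumerate(pk):
        start = p - spec.peak_index
        end = start + spec.window_frames
        if i > 0 and pk[i - 1] > start:
            start = max(start, pk[i - 1] + spec.margin_frames)
        if i + 1 < len(pk) and pk[i + 1] < end:
            end = min(end, pk[i + 1] - spec.margin_frames)
        start = max(start, win_lo)
        end = min(end, win_hi)
        if end <= start or not (win_lo <= p < win_hi):
            continue
        kept.append(i)
        valid.append((start - (p - spec.peak_index), end - (p - spec.peak_index)))

    valid_arr = np.asarray(valid, int).reshape(-1, 2)
    traces: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        out = np.full((len(kept), spec.window_frames) + arr.shape[1:], np.nan)
        for row, (i, (v0, v1)) in enumerate(zip(kept, valid)):
            src0 = pk[i] - spec.peak_index + v0
            out[row, v0:v1] = arr[src0 : src0 + (v1 - v0)]
        traces[name] = out

    return StepEnsemble(
        spec=spec,
        fps=peaks.fps,
        peak_frames=pk[kept],
        valid=valid_arr,
        traces=traces,
        n_dropped=len(pk) - len(kept),
    )


def average_steps(
    ensemble: StepEnsemble,
    height_trace: str | None = None,
    smooth_window: int = 11,
    velocity_fraction: float = 0.1,
) -> StepAverage:
    """Pointwise mean over steps, truncated tails excluded from the denominator.

    If ``height_trace`` names an averaged tarsal-tip-height trace, the swing
    interval is inferred from it: the averaged height is smoothed with a local
    quadratic (Savitzky-Golay) filter and the swing bout around the alignment
    peak is delimited where the vertical velocity crosses ``velocity_fraction``
    of its peak magnitude — rising through it before the peak (lift-off) and
    returning above its negative after the peak (touch-down).
    """
    if ensemble.n_steps == 0:
        raise ValueError("cannot average an empty ensemble")
    first = next(iter(ensemble.traces.values()))
    counts = np.sum(np.isfinite(first.reshape(first.shape[:2] + (-1,))[..., 0]), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        traces = {k: np.nanmean(v, axis=0) for k, v in ensemble.traces.items()}

    swing = None
    if height_trace is not None:
        swing = _infer_swing_interval(
            traces[height_trace],
            ensemble.spec.peak_index,
            smooth_window,
            velocity_fraction,
        )
    return StepAverage(traces=traces, counts=counts, swing_interval=swing)


def _infer_swing_interval(
    height: np.ndarray, peak_index: int, smooth_window: int, fraction: float
) -> tuple[int, int] | None:
    height = np.asarray(height, float)
    finite = np.isfinite(height)
    if finite.sum() < smooth_window or not finite[peak_index]:
        return None
    lo = peak_index
    while lo > 0 and finite[lo - 1]:
        lo -= 1
    hi = peak_index
    while hi < len(height) - 1 and finite[hi + 1]:
        hi += 1
    seg = height[lo : hi + 1]
    if len(seg) < smooth_window:
        return None
    vel = signal.savgol_filter(seg, smooth_window, 2, deriv=1)
    thr = fraction * np.max(np.abs(vel))
    p = peak_index - lo

    # lift-off: walk back from the peak into the rising flank, then past it
    i = p
    while i > 0 and vel[i] < thr:
        i -= 1
    while i > 0 and vel[i] >= thr:
        i -= 1
    start = i + 1 if vel[i] < thr else i
    # touch-down: walk forward into the falling flank, then past it
    j = p
    while j < len(seg) - 1 and vel[j] > -thr:
        j += 1
    while j < len(seg) - 1 and vel[j] <= -thr:
        j += 1
    end = j if vel[j] <= -thr else j
    if end <= start:
        return None
    return (start + lo, end + lo + 1)


def step_geometry(trajectory: np.ndarray) -> StepGeometry:
    """Extreme positions and geometry of one step's tarsal-tip trajectory.

    AEP is the anterior-most (max-x) point, PEP the posterior-most (min-x),
    DEP the dorsal-most (max-y).  Step size is |AEP - PEP|; swing-stroke
    amplitude is the distance from DEP to the closed segment AEP-PEP.
    """
    traj = np.asarray(trajectory, float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must have shape (n, 2)")
    traj = traj[np.all(np.isfinite(traj), axis=1)]
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    aep = traj[np.argmax(traj[:, 0])]
    pep = traj[np.argmin(traj[:, 0])]
    dep = traj[np.argmax(traj[:, 1])]
    step_size = float(np.linalg.norm(aep - pep))
    n_distinct = len(np.unique(traj, axis=0))
    if n_distinct < 3:
        return StepGeometry(aep, pep, dep, step_size, np.nan, well_defined=False)
    amp = point_to_segment_distance(dep, aep, pep)
    return StepGeometry(aep, pep, dep, step_size, amp, well_defined=True)


def point_to_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance from point ``p`` to the closed segment ``a``-``b``."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def step_frequency(peaks: SwingPeakSet) -> float:
    """Reciprocal of the mean interval between neighbouring swing peaks (Hz)."""
    if len(peaks) < 2:
        raise ValueError("step frequency requires at least 2 swing peaks")
    return float(1.0 / np.mean(np.diff(peaks.times_s)))


def joint_angle_range(angle_trace: np.ndarray) -> float:
    """Maximum minus minimum of a (per-step) joint-angle trace, degrees."""
    trace = np.asarray(angle_trace, float)
    if not np.isfinite(trace).any():
        return np.nan
    return float(np.nanmax(trace) - np.nanmin(trace))


def max_flexion(
    angle_trace: np.ndarray,
    fps: float,
    onset_s: float,
    window_s: float = 1.0,
    reextension_deg: float = 5.0,
) -> float:
    """Maximal joint flexion after stimulus onset, stopped at re-extension.

    Returns the minimum angle reached within ``window_s`` after ``onset_s``,
    evaluated only up to the first re-extension event — the first local
    minimum that is followed, within the window, by a rise exceeding
    ``reextension_deg``.  Without such an event the whole window counts.
    """
    trace = np.asarray(angle_trace, float)
    i0 = int(round(onset_s * fps))
    i1 = int(round((onset_s + window_s) * fps))
    if i0 < 0 or i1 > len(trace):
        raise ValueError("trace does not cover the requested window")
    win = trace[i0:i1]
    if not np.isfinite(win).any():
        raise ValueError("all-NaN analysis window")
    minima, _ = signal.find_peaks(-win)
    for m in minima:
        if np.nanmax(win[m:]) - win[m] > reextension_deg:
            return float(np.nanmin(win[: m + 1]))
    return float(np.nanmin(win))


def min_step_angle(step_angle_trace: np.ndarray, peak_index: int) -> float:
    """Minimum joint angle over the pre-swing-peak portion of a step."""
    trace = np.asarray(step_angle_trace, float)
    pre = trace[:peak_index]
    if pre.size == 0 or not np.isfinite(pre).any():
        warnings.warn("no pre-peak frames; minimum stance angle undefined")
        return np.nan
    return float(np.nanmin(pre))


def flexion_slope(avg_angle_trace: np.ndarray, fps: float) -> float:
    """OLS slope (degrees/s) of the declining flank of an averaged step.

    Fits a straight line from the trace's maximum to the end of the window;
    a negative slope quantifies flexion speed.
    """
    trace = np.asarray(avg_angle_trace, float)
    if not np.isfinite(trace).any():
        raise ValueError("all-NaN trace")
    start = int(np.nanargmax(trace))
    seg = trace[start:]
    t = np.arange(len(seg)) / fps
    ok = np.isfinite(seg)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 points in the fit range")
    return float(np.polyfit(t[ok], seg[ok], 1)[0])
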