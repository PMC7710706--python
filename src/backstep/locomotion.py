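"""Arena-level locomotion: heading-projected speed and walking distances.

Centroid tracks (per-frame x, y in mm and heading in radians, 30 frames/s by
default) yield a signed speed along the heading; integrating it over stimulus
episodes with a backward-speed threshold gives per-fly backward distance, and
over the pre-stimulus window (no threshold) the net forward distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_ARENA_FPS = 30.0
BACKWARD_SPEED_THRESHOLD = 1.5  # mm/s


@dataclass
class CentroidTrack:
    """Arena track of one fly: positions (mm) and heading (rad) per frame."""

    fly_id: str
    xy: np.ndarray  # (n_frames, 2)
    heading: np.ndarray  # (n_frames,)
    fps: float = DEFAULT_ARENA_FPS

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, float)
        self.heading = np.asarray(self.heading, float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n_frames, 2)")
        if self.heading.shape != (self.xy.shape[0],):
            raise ValueError("heading must be defined for every frame")
        if not (np.isfinite(self.xy).all() and np.isfinite(self.heading).all()):
            raise ValueError("track contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]


@dataclass(frozen=True)
class EpisodeSchedule:
    """Stimulus episodes (onset_s, duration_s) plus the pre-stimulus window."""

    episodes: tuple[tuple[float, float], ...]
    pre_window_s: float = 45.0

    def __post_init__(self) -> None:
        eps = sorted(self.episodes)
        for (o1, d1), (o2, _) in zip(eps, eps[1:]):
            if o1 + d1 > o2:
                raise ValueError("episodes overlap")

    @property
    def total_episode_s(self) -> float:
        return sum(d for _, d in self.episodes)


def flybowl_schedule(
    n_episodes: int = 9,
    episode_s: float = 5.0,
    first_onset_s: float = 60.0,
    interval_s: float = 60.0,
    pre_window_s: float = 45.0,
) -> EpisodeSchedule:
    """Standard open-arena protocol: nine 5-s episodes, one per minute."""
    return EpisodeSchedule(
        episodes=tuple(
            (first_onset_s + i * interval_s, episode_s) for i in range(n_episodes)
        ),
        pre_window_s=pre_window_s,
    )


def heading_speed(track: CentroidTrack) -> np.ndarray:
    """Signed per-frame speed along the heading, mm/s (positive = forward).

    The frame-to-frame displacement is projected onto the heading of the
    earlier frame; sideways motion contributes nothing.  Returns n_frames - 1
    values, one per frame interval.
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    disp = np.diff(track.xy, axis=0) * track.fps
    h = track.heading[:-1]
    return disp[:, 0] * np.cos(h) + disp[:, 1] * np.sin(h)


def _interval_mask(n_intervals: int, fps: float, start_s: float, end_s: float):
    t = np.arange(n_intervals) / fps
    return (t >= start_s) & (t < end_s)


def backward_distance(
    track: CentroidTrack,
    schedule: EpisodeSchedule,
    threshold_mm_s: float = BACKWARD_SPEED_THRESHOLD,
) -> float:
    """Accumulated backward distance (mm) over the stimulus episodes.

    Frame intervals within an episode whose heading-projected speed is at or
    below ``-threshold_mm_s`` contribute |v|*dt; slower frames contribute 0.
    """
    v = heading_speed(track)
    last_end = max(o + d for o, d in schedule.episodes)
    if track.n_frames / track.fps < last_end:
        raise ValueError("track shorter than the episode schedule")
    dt = 1.0 / track.fps
    total = 0.0
    for onset, dur in schedule.episodes:
        m = _interval_mask(len(v), track.fps, onset, onset + dur)
        vv = v[m]
        total += float(np.sum(-vv[vv <= -threshold_mm_s]) * dt)
    return total


def forward_distance(track: CentroidTrack, window_s: float = 45.0) -> float:
    """Net signed forward displacement (mm) along heading in the early window."""
    v = heading_speed(track)
    if track.n_frames / track.fps < window_s:
        raise ValueError("window exceeds the track")
    m = _interval_mask(len(v), track.fps, 0.0, window_s)
    return float(np.sum(v[m]) / track.fps)


def cohort_summary(
    tracks: list[CentroidTrack],
    schedule: EpisodeSchedule,
    threshold_mm_s: float = BACKWARD_SPEED_THRESHOLD,
) -> pd.DataFrame:
    """Per-fly distances plus a cohort mean ± s.e.m. row.

    Returns one row per fly (``fly_id``, ``backward_mm``, ``forward_mm``) and
    a final ``cohort`` row carrying the means; s.e.m. is NaN for a single fly.
    """
    if not tracks:
        raise ValueError("need at least one track")
    rows = [
        {
            "fly_id": tr.fly_id,
            "backward_mm": backward_distance(tr, schedule, threshold_mm_s),
            "forward_mm": forward_distance(tr, schedule.pre_window_s),
        }
        for tr in tracks
    ]
    df = pd.DataFrame(rows)
    n = len(df)
    sem = df[["backward_mm", "forward_mm"]].std(ddof=1) / np.sqrt(n) if n > 1 else None
    cohort = {
        "fly_id": "cohort",
        "backward_mm": df["backward_mm"].mean(),
        "forward_mm": df["forward_mm"].mean(),
        "backward_sem": np.nan if sem is None else sem["backward_mm"],
        "forward_sem": np.nan if sem is None else sem["forward_mm"],
    }
    return pd.concat([df, pd.DataFrame([cohort])], ignore_index=True)


# ---------------------------------------------------------------------------
# file I/O (flat CSV: fly_id, frame, x_mm, y_mm, heading_rad)


def read_tracks(path: str | Path, fps: float = DEFAULT_ARENA_FPS) -> list[CentroidTrack]:
    df = pd.read_csv(path)
    required = {"fly_id", "frame", "x_mm", "y_mm", "heading_rad"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file is missing columns: {sorted(missing)}")
    tracks = []
    for fly_id, sub in df.groupby("fly_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(
            CentroidTrack(
                fly_id=str(fly_id),
                xy=sub[["x_mm", "y_mm"]].to_numpy(float),
                heading=sub["heading_rad"].to_numpy(float),
                fps=fps,
            )
        )
    return tracks


def write_tracks(tracks: list[CentroidTrack], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "frame": np.arange(tr.n_frames),
                    "x_mm": tr.xy[:, 0],
                    "y_mm": tr.xy[:, 1],
                    "heading_rad": tr.heading,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
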