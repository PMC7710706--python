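"""Synthetic open-arena centroid tracks with known backward-walking bouts.

Responder flies walk anti-parallel to their heading at a fixed backward speed
during stimulus episodes and forward between them; non-responders always walk
forward.  Heading follows a seeded random walk.  Because displacement uses the
earlier frame's heading, the locomotion module recovers the programmed
distances up to threshold effects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..locomotion import CentroidTrack, EpisodeSchedule, flybowl_schedule


@dataclass(frozen=True)
class ArenaSimParams:
    """Cohort simulation parameters (speeds in mm/s)."""

    n_flies: int = 10
    fps: float = 30.0
    schedule: EpisodeSchedule = field(default_factory=flybowl_schedule)
    backward_speed_mm_s: float = 5.0
    forward_speed_mm_s: float = 10.0
    responder_fraction: float = 1.0
    heading_noise_rad: float = 0.05
    duration_s: float | None = None  # default: 10 s past the last episode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backward_speed_mm_s < 0 or self.forward_speed_mm_s < 0:
            raise ValueError("speeds must be non-negative")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder fraction must lie in [0, 1]")
        if self.n_flies < 1 or self.fps <= 0:
            raise ValueError("need at least one fly and a positive frame rate")


def simulate_arena(params: ArenaSimParams) -> tuple[list[CentroidTrack], pd.DataFrame]:
    """Generate per-fly tracks plus a ground-truth table.

    Returns the tracks and a DataFrame with columns ``fly_id``, ``responder``,
    ``backward_mm_true`` (programmed backward distance over all episodes) and
    ``forward_mm_true`` (programmed forward distance in the pre-stimulus
    window).  Per-fly random streams are spawned from the master seed.
    """
    sched = params.schedule
    duration = (
        params.duration_s
        if params.duration_s is not None
        else max(o + d for o, d in sched.episodes) + 10.0
    )
    n = int(round(duration * params.fps))
    dt = 1.0 / params.fps
    t = np.arange(n) * dt

    in_episode = np.zeros(n, bool)
    for onset, dur in sched.episodes:
        in_episode |= (t >= onset) & (t < onset + dur)

    n_resp = int(round(params.responder_fraction * params.n_flies))
    tracks, truth = [], []
    for fi in range(params.n_flies):
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(fi,)))
        responder = fi < n_resp
        heading = np.cumsum(
            np.r_[rng.uniform(-np.pi, np.pi), rng.normal(0, params.heading_noise_rad, n - 1)]
        )
        speed = np.full(n, params.forward_speed_mm_s)
        if responder:
            speed[in_episode] = -params.backward_speed_mm_s
        # displacement over interval i uses the heading at its earlier frame
        step = (speed * dt)[:-1, None] * np.stack(
            [np.cos(heading[:-1]), np.sin(heading[:-1])], axis=-1
        )
        xy = np.vstack([[0.0, 0.0], np.cumsum(step, axis=0)])
        tracks.append(
            CentroidTrack(fly_id=f"fly{fi:03d}", xy=xy, heading=heading, fps=params.fps)
        )

        # programmed truths over the same frame intervals the analysis uses
        v = speed[:-1]
        backward_true = float(np.sum(np.maximum(0.0, -v[in_episode[:-1]])) * dt)
        forward_true = float(np.sum(v[t[:-1] < sched.pre_window_s]) * dt)
        truth.append(
            {
                "fly_id": f"fly{fi:03d}",
                "responder": responder,
                "backward_mm_true": backward_true,
                "forward_mm_true": forward_true,
            }
        )
    return tracks, pd.DataFrame(truth)
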