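"""Pose tables: the per-frame landmark container and its file dialects.

Two dialects are supported.  The pose-estimation dialect has three header rows
(scorer / bodyparts / coords) with an x, y, likelihood column triplet per
landmark and image coordinates (y grows downward); the reader flips y into the
package's y-up analysis frame.  The plain dialect is a single-header CSV with
``<landmark>_x, <landmark>_y, <landmark>_conf`` columns already in the
analysis frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bodyplan import LEG_IDS, leg_landmarks

DEFAULT_FPS = 200.0


@dataclass
class PoseSeries:
    """Per-frame 2-D landmark coordinates + confidences for one tracked fly.

    ``coords`` has shape (n_frames, n_landmarks, 2) in the y-up analysis frame;
    ``confidence`` has shape (n_frames, n_landmarks) with values in [0, 1].
    """

    fps: float
    landmark_names: tuple[str, ...]
    coords: np.ndarray
    confidence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.landmark_names):
            raise ValueError("coords must have shape (n_frames, n_landmarks, 2)")
        if self.confidence is None:
            self.confidence = np.ones(self.coords.shape[:2])
        self.confidence = np.asarray(self.confidence, float)
        if self.confidence.shape != self.coords.shape[:2]:
            raise ValueError("confidence shape must match (n_frames, n_landmarks)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def _index(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not in pose table") from None

    def xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinates of one landmark."""
        return self.coords[:, self._index(name), :]

    def conf(self, name: str) -> np.ndarray:
        return self.confidence[:, self._index(name)]

    def leg_points(self, leg_id: str) -> np.ndarray:
        """(n_frames, 5, 2) landmark stack for one leg, proximal to distal."""
        idx = [self._index(n) for n in leg_landmarks(leg_id)]
        return self.coords[:, idx, :]

    def leg_conf(self, leg_id: str) -> np.ndarray:
        idx = [self._index(n) for n in leg_landmarks(leg_id)]
        return self.confidence[:, idx]

    def legs_present(self) -> tuple[str, ...]:
        names = set(self.landmark_names)
        return tuple(
            leg for leg in LEG_IDS if all(n in names for n in leg_landmarks(leg))
        )


def require_legs(pose: PoseSeries, legs: tuple[str, ...]) -> None:
    """Raise with the missing landmark names if any leg is incomplete."""
    names = set(pose.landmark_names)
    missing = [
        n for leg in legs for n in leg_landmarks(leg) if n not in names
    ]
    if missing:
        raise ValueError(f"pose table is missing required landmarks: {missing}")


def read_pose_table(
    path: str | Path, fps: float = DEFAULT_FPS, required_legs: tuple[str, ...] = ()
) -> PoseSeries:
    """Read a pose CSV in either supported dialect.

    The pose-estimation dialect is detected from its ``scorer`` header cell;
    its image y-coordinates are negated into the y-up analysis frame.  The
    frame rate is not stored in either dialect and must be supplied.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.split(",")[0].strip().lower() == "scorer":
        pose = _read_dlc(path, fps)
    else:
        pose = _read_plain(path, fps)
    if required_legs:
        require_legs(pose, required_legs)
    return pose


def _read_dlc(path: Path, fps: float) -> PoseSeries:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
    coords, confs = [], []
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for col in ("x", "y", "likelihood"):
            if col not in sub.columns:
                raise ValueError(
                    f"malformed pose table: landmark {bp!r} lacks a {col!r} column"
                )
        x = sub["x"].to_numpy(float)
        y = -sub["y"].to_numpy(float)  # image frame -> y-up analysis frame
        coords.append(np.stack([x, y], axis=-1))
        confs.append(sub["likelihood"].to_numpy(float))
    return PoseSeries(
        fps=fps,
        landmark_names=tuple(bodyparts),
        coords=np.stack(coords, axis=1),
        confidence=np.stack(confs, axis=1),
    )


def _read_plain(path: Path, fps: float) -> PoseSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            names.append(col[:-2])
    if not names:
        raise ValueError("plain pose CSV has no <landmark>_x columns")
    coords, confs = [], []
    for name in names:
        for suffix in ("_x", "_y"):
            if name + suffix not in df.columns:
                raise ValueError(f"landmark {name!r} lacks the {suffix} column")
        coords.append(df[[name + "_x", name + "_y"]].to_numpy(float))
        if name + "_conf" in df.columns:
            confs.append(df[name + "_conf"].to_numpy(float))
        else:
            confs.append(np.ones(len(df)))
    return PoseSeries(
        fps=fps,
        landmark_names=tuple(names),
        coords=np.stack(coords, axis=1),
        confidence=np.stack(confs, axis=1),
    )


def write_pose_table(
    pose: PoseSeries, path: str | Path, scorer: str = "backstep_synth"
) -> None:
    """Write a PoseSeries in the three-header pose-estimation dialect.

    Analysis-frame y is negated back into image coordinates so that
    write -> read round-trips exactly.
    """
    cols = pd.MultiIndex.from_tuples(
        [
            (scorer, name, coord)
            for name in pose.landmark_names
            for coord in ("x", "y", "likelihood")
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    n = pose.n_frames
    data = np.empty((n, 3 * len(pose.landmark_names)))
    for i, _name in enumerate(pose.landmark_names):
        data[:, 3 * i] = pose.coords[:, i, 0]
        data[:, 3 * i + 1] = -pose.coords[:, i, 1]
        data[:, 3 * i + 2] = pose.confidence[:, i]
    # %.17g guarantees float64 values survive the text round trip bit-exactly
    pd.DataFrame(data, columns=cols).to_csv(path, float_format="%.17g")
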