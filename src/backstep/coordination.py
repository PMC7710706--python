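"""Interleg coordination from footfall patterns.

A footfall pattern is a legs x frames boolean matrix (True = swing).  The
coordination score between two legs is the co-swing index: frames both legs
are in swing divided by frames either is, over a half-open frame window.
Pairs are classified by laterality (ipsi/contralateral) and segment
(intra/intersegmental); a hexapod has 15 unordered pairs, of which 3 are
intrasegmental and 12 intersegmental.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .bodyplan import LEG_IDS
from .pose import PoseSeries


@dataclass
class FootfallPattern:
    """Per-leg, per-frame swing/stance matrix (True = swing)."""

    mask: np.ndarray  # (n_legs, n_frames) bool
    fps: float
    legs: tuple[str, ...] = LEG_IDS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != len(self.legs):
            raise ValueError("mask must have shape (n_legs, n_frames)")
        if len(set(self.legs)) != len(self.legs):
            raise ValueError("leg labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.mask.shape[1]

    def leg(self, leg_id: str) -> np.ndarray:
        try:
            return self.mask[self.legs.index(leg_id)]
        except ValueError:
            raise KeyError(f"unknown leg label {leg_id!r}") from None


@dataclass(frozen=True)
class PairClass:
    """Classification of an unordered leg pair."""

    pair: tuple[str, str]
    laterality: str  # "ipsilateral" | "contralateral"
    segmental: str  # "intrasegmental" | "intersegmental"


def classify_pair(leg_a: str, leg_b: str) -> PairClass:
    if leg_a == leg_b:
        raise ValueError("a pair needs two distinct legs")
    side_a, seg_a = leg_a[0], leg_a[1]
    side_b, seg_b = leg_b[0], leg_b[1]
    return PairClass(
        pair=(leg_a, leg_b),
        laterality="ipsilateral" if side_a == side_b else "contralateral",
        segmental="intrasegmental" if seg_a == seg_b else "intersegmental",
    )


def _despeckle(mask: np.ndarray, min_bout: int) -> np.ndarray:
    """Remove swing and stance runs shorter than ``min_bout`` frames."""
    out = mask.copy()
    for target in (True, False):  # short swing bouts first, then short gaps
        edges = np.flatnonzero(np.diff(np.r_[~target, out == target, ~target]))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start < min_bout:
                out[start:end] = not target
    return out


def swing_mask(
    source: PoseSeries | str | Path,
    method: str = "height",
    z_threshold: float = 0.5,
    min_bout_frames: int = 3,
    fps: float | None = None,
) -> FootfallPattern:
    """Per-frame swing/stance labels for all legs.

    ``method="labels"`` passes through a frame x leg boolean CSV annotation
    file unchanged.  ``method="height"`` thresholds each leg's z-scored
    tarsal-tip height: frames at or above ``z_threshold`` seed swing bouts,
    which are extended down to just above the stance floor (hysteresis), and
    bouts or gaps shorter than ``min_bout_frames`` are removed.
    """
    if method == "labels":
        df = pd.read_csv(source)
        unknown = [c for c in df.columns if c not in LEG_IDS]
        if unknown:
            raise ValueError(f"unknown leg labels in annotation file: {unknown}")
        legs = tuple(c for c in LEG_IDS if c in df.columns)
        mask = df[list(legs)].to_numpy(bool).T
        return FootfallPattern(mask, fps=fps or 200.0, legs=legs)
    if method != "height":
        raise ValueError(f"unknown method {method!r}")

    pose: PoseSeries = source  # type: ignore[assignment]
    legs = pose.legs_present()
    if not legs:
        raise ValueError("pose table contains no complete leg")
    rows = []
    for leg in legs:
        y = pose.xy(f"{leg}_tarsal_tip")[:, 1]
        rows.append(_height_swing(y, z_threshold, min_bout_frames))
    return FootfallPattern(np.array(rows), fps=pose.fps, legs=legs)


def _height_swing(y: np.ndarray, z_threshold: float, min_bout: int) -> np.ndarray:
    y = np.asarray(y, float)
    sd = np.nanstd(y)
    if sd == 0 or not np.isfinite(y).any():
        return np.zeros(len(y), bool)
    z = (y - np.nanmean(y)) / sd
    seeds = z >= z_threshold
    # hysteresis floor: just above the stance level (5th percentile of height)
    floor = np.nanpercentile(z, 5.0)
    low = z > floor + 0.05 * (np.nanmax(z) - floor)
    mask = _grow_from_seeds(seeds, low)
    return _despeckle(mask, min_bout)


def _grow_from_seeds(seeds: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Keep every contiguous True-run of ``low`` that contains a seed frame."""
    out = np.zeros_like(low)
    edges = np.flatnonzero(np.diff(np.r_[False, low, False]))
    for start, end in zip(edges[::2], edges[1::2]):
        if seeds[start:end].any():
            out[start:end] = True
    return out


def co_swing_index(
    pattern: FootfallPattern,
    leg_a: str,
    leg_b: str,
    window: tuple[int, int] | None = None,
) -> float:
    """Co-swing index of a leg pair over a half-open frame window.

    Frames both legs swing divided by frames either swings; NaN (flagged by a
    warning upstream) when neither leg ever swings in the window.
    """
    a = pattern.leg(leg_a)
    b = pattern.leg(leg_b)
    if window is not None:
        lo, hi = window
        if lo < 0 or hi > pattern.n_frames or hi <= lo:
            raise ValueError("window outside the recording")
        a, b = a[lo:hi], b[lo:hi]
    union = int(np.sum(a | b))
    if union == 0:
        return np.nan
    return float(np.sum(a & b) / union)


def pairwise_summary(
    pattern: FootfallPattern, window: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Co-swing index and classification for all unordered leg pairs.

    Returns one row per pair with columns ``leg_a, leg_b, laterality,
    segmental, group, co_swing_index`` where ``group`` is intrasegmental /
    intersegmental_ipsi / intersegmental_contra.
    """
    if len(pattern.legs) < 2:
        raise ValueError("need at least 2 legs")
    rows = []
    for leg_a, leg_b in combinations(pattern.legs, 2):
        cls = classify_pair(leg_a, leg_b)
        if cls.segmental == "intrasegmental":
            group = "intrasegmental"
        else:
            suffix = "ipsi" if cls.laterality == "ipsilateral" else "contra"
            group = f"intersegmental_{suffix}"
        rows.append(
            {
                "leg_a": leg_a,
                "leg_b": leg_b,
                "laterality": cls.laterality,
                "segmental": cls.segmental,
                "group": group,
                "co_swing_index": co_swing_index(pattern, leg_a, leg_b, window),
            }
        )
    return pd.DataFrame(rows)


def group_means(summary: pd.DataFrame, by: str = "group") -> pd.Series:
    """Mean co-swing index per pair class (grouping column is configurable)."""
    return summary.groupby(by)["co_swing_index"].mean()
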