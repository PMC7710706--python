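"""Phase-coupled hexapod gait generator with exact kinematic ground truth.

Each leg's tarsal tip follows a prescribed step cycle — a stance segment at
ground height between the anterior (AEP) and posterior (PEP) extreme
positions and a half-ellipse swing arc peaking at ``swing_height`` — and the
remaining landmarks are placed by closed-form two-link inverse kinematics
(body-coxa angle held fixed, tarsus collinear with the tibia).  Joint angles,
landmarks and the tip path are therefore mutually exact: at zero landmark
noise, recomputing angles from the landmarks reproduces the stored truth to
floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..bodyplan import (
    BODY_AXIS_LANDMARKS,
    LEG_IDS,
    LegChainSpec,
    angles_from_landmarks,
    default_body_plan,
    leg_landmarks,
)
from ..coordination import FootfallPattern
from ..pose import PoseSeries


def tripod_offsets() -> dict[str, float]:
    """Tripod coupling: {LF, RM, LH} in phase, {RF, LM, RH} in antiphase."""
    return {"LF": 0.0, "RM": 0.0, "LH": 0.0, "RF": 0.5, "LM": 0.5, "RH": 0.5}


@dataclass(frozen=True)
class GaitParams:
    """Step-cycle parameters shared by all legs.

    ``aep_x``/``pep_x`` are tip extremes relative to each leg's anchor x in
    the anterior-positive analysis frame (aep_x > pep_x); ``duty_factor`` is
    the stance fraction of the cycle; ``phase_offsets`` maps leg to cycle
    phase in [0, 1).
    """

    step_frequency_hz: float = 2.0
    duty_factor: float = 0.5
    phase_offsets: dict[str, float] = field(default_factory=tripod_offsets)
    direction: str = "forward"
    aep_x: float = 1.0
    pep_x: float = -1.0
    swing_height: float = 0.4
    body_coxa_angle_deg: float = 120.0
    landmark_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_frequency_hz <= 0:
            raise ValueError("step frequency must be positive")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty factor must lie in (0, 1)")
        if self.aep_x <= self.pep_x:
            raise ValueError("aep_x must exceed pep_x (anterior-positive frame)")
        if self.swing_height < 0 or self.landmark_noise_sd < 0:
            raise ValueError("swing height and noise sd must be non-negative")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        for leg, off in self.phase_offsets.items():
            if not 0 <= off < 1:
                raise ValueError(f"phase offset of {leg} outside [0, 1)")


@dataclass
class SyntheticPoseDataset:
    """Generated pose plus the ground truth every downstream stage can test."""

    pose: PoseSeries
    true_angles: dict[str, np.ndarray]  # leg -> (n_frames, 4) degrees
    true_swing_mask: FootfallPattern
    true_tip: dict[str, np.ndarray]  # leg -> (n_frames, 2) noise-free tip
    params: GaitParams
    chains: dict[str, LegChainSpec]


def _tip_cycle(params: GaitParams, phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tip (x_rel, y) over the cycle phase; also used as the swing-mask rule."""
    duty = params.duty_factor
    aep, pep = params.aep_x, params.pep_x
    if params.direction == "backward":
        aep, pep = pep, aep  # stance traverses PEP -> AEP when walking backward
    in_stance = phase < duty
    x = np.where(
        in_stance,
        aep + (pep - aep) * (phase / duty),
        pep + (aep - pep) * ((phase - duty) / (1 - duty)),
    )
    y = np.where(
        in_stance,
        0.0,
        params.swing_height * np.sin(np.pi * (phase - duty) / (1 - duty)),
    )
    return x, y


def _leg_landmarks_from_tip(
    chain: LegChainSpec, tip: np.ndarray, body_coxa_deg: float
) -> np.ndarray:
    """Pose the leg so its tarsal tip hits ``tip``; returns (n, 5, 2).

    Two-link closed-form inverse kinematics: coxa direction fixed by the
    body-coxa angle, femur as the first link, tibia+tarsus (collinear) as the
    second; the knee is placed on the side that bends the chain in the same
    clockwise sense as :func:`backstep.bodyplan.forward_kinematics`.
    """
    lc, lf, lt, lta = chain.segment_lengths
    l2 = lt + lta
    rad = np.deg2rad(body_coxa_deg)
    c0 = np.asarray(chain.anchor, float)
    c1 = c0 + lc * np.array([np.cos(rad), -np.sin(rad)])

    r = tip - c1
    d = np.linalg.norm(r, axis=-1)
    lo, hi = abs(lf - l2), lf + l2
    if np.any(d <= lo) or np.any(d >= hi):
        raise ValueError(
            f"{chain.leg_id}: tip target out of reach "
            f"(d range [{d.min():.3f}, {d.max():.3f}], reach ({lo:.3f}, {hi:.3f}))"
        )
    # angle at the coxa-trochanter joint between the chord and the femur
    alpha = np.arccos(np.clip((lf**2 + d**2 - l2**2) / (2 * lf * d), -1, 1))
    u = r / d[:, None]
    ca, sa = np.cos(alpha), np.sin(alpha)
    u1 = np.stack(
        [ca * u[:, 0] - sa * u[:, 1], sa * u[:, 0] + ca * u[:, 1]], axis=-1
    )
    knee = c1 + lf * u1
    u2 = (tip - knee) / l2
    tt = knee + lt * u2
    n = len(tip)
    return np.stack(
        [np.broadcast_to(c0, (n, 2)), np.broadcast_to(c1, (n, 2)), knee, tt, tip],
        axis=1,
    )


def simulate_gait(
    params: GaitParams,
    chains: dict[str, LegChainSpec] | None = None,
    duration_s: float = 5.0,
    fps: float = 200.0,
) -> SyntheticPoseDataset:
    """Generate a phase-coupled hexapod walking bout with full ground truth.

    Noise streams are spawned per leg from the master seed, so adding a leg
    (or changing another leg's noise) never perturbs existing legs.
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration must be positive")
    if duration_s * params.step_frequency_hz < 2:
        raise ValueError("need at least 2 full step cycles")
    chains = chains if chains is not None else default_body_plan()

    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    root = np.random.SeedSequence(params.seed)

    names: list[str] = []
    coords: list[np.ndarray] = []
    true_angles: dict[str, np.ndarray] = {}
    true_tip: dict[str, np.ndarray] = {}
    swing_rows = []
    legs = tuple(leg for leg in LEG_IDS if leg in chains)
    for li, leg in enumerate(legs):
        chain = chains[leg]
        offset = params.phase_offsets.get(leg, 0.0)
        phase = np.mod(params.step_frequency_hz * t + offset, 1.0)
        x_rel, y = _tip_cycle(params, phase)
        tip = np.stack([chain.anchor[0] + x_rel, y], axis=-1)
        lm = _leg_landmarks_from_tip(chain, tip, params.body_coxa_angle_deg)

        true_tip[leg] = tip
        true_angles[leg] = angles_from_landmarks(lm)
        swing_rows.append(phase >= params.duty_factor)

        if params.landmark_noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(params.seed, spawn_key=(li,))
            )
            lm = lm + rng.normal(0.0, params.landmark_noise_sd, lm.shape)
        names.extend(leg_landmarks(leg))
        coords.append(lm)

    # midline landmarks defining the (static) anterior body axis
    body_y = float(np.mean([chains[leg].anchor[1] for leg in legs]))
    span = max(abs(chains[leg].anchor[0]) for leg in legs) + 1.5
    body_pts = np.broadcast_to(
        np.array([[span, body_y], [-span, body_y]]), (n, 2, 2)
    ).copy()
    if params.landmark_noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(params.seed, spawn_key=(len(LEG_IDS),))
        )
        body_pts += rng.normal(0.0, params.landmark_noise_sd, body_pts.shape)
    names.extend(BODY_AXIS_LANDMARKS)

    all_coords = np.concatenate(coords + [body_pts], axis=1)
    pose = PoseSeries(fps=fps, landmark_names=tuple(names), coords=all_coords)
    mask = FootfallPattern(np.array(swing_rows), fps=fps, legs=legs)
    return SyntheticPoseDataset(
        pose=pose,
        true_angles=true_angles,
        true_swing_mask=mask,
        true_tip=true_tip,
        params=params,
        chains=chains,
    )
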