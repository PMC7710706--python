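"""Hexapod body plan: leg identities, landmark naming, and planar leg kinematics.

The analysis frame used throughout the package is side-view, 2-D,
anterior-positive x and dorsal-positive (y-up).  Each leg is a planar chain of
four segments (coxa, femur, tibia, tarsus) hinged at four joints (body-coxa,
coxa-trochanter, femur-tibia, tibia-tarsus), giving five tracked landmarks per
leg from the body-coxa joint to the tarsal tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical leg labels: Left/Right x Fore/Mid/Hind.
LEG_IDS = ("LF", "LM", "LH", "RF", "RM", "RH")

#: Landmark name suffixes, proximal to distal.
LANDMARK_SUFFIXES = (
    "body_coxa",
    "coxa_trochanter",
    "femur_tibia",
    "tibia_tarsus",
    "tarsal_tip",
)

#: Joint names in the same order as the four angles of a leg chain.
JOINT_NAMES = ("body_coxa", "coxa_trochanter", "femur_tibia", "tibia_tarsus")

#: Midline landmarks defining the body axis (anterior point first).
BODY_AXIS_LANDMARKS = ("body_anterior", "body_posterior")


def leg_landmarks(leg_id: str) -> tuple[str, ...]:
    """Full landmark names for one leg, e.g. ``LH_femur_tibia``."""
    if leg_id not in LEG_IDS:
        raise ValueError(f"unknown leg id {leg_id!r}; expected one of {LEG_IDS}")
    return tuple(f"{leg_id}_{s}" for s in LANDMARK_SUFFIXES)


@dataclass(frozen=True)
class LegChainSpec:
    """Geometry of one leg: anchor point and the four segment lengths (mm).

    ``anchor`` is the body-coxa joint position in the analysis frame;
    ``segment_lengths`` are (coxa, femur, tibia, tarsus).
    """

    leg_id: str
    anchor: tuple[float, float]
    segment_lengths: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.leg_id not in LEG_IDS:
            raise ValueError(f"unknown leg id {self.leg_id!r}")
        if len(self.segment_lengths) != 4:
            raise ValueError("a leg chain has exactly 4 segments")
        if any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment lengths must all be positive")


def default_body_plan(
    segment_lengths: tuple[float, float, float, float] = (0.8, 1.6, 1.4, 0.8),
    body_height: float = 2.5,
    segment_spacing: float = 2.0,
) -> dict[str, LegChainSpec]:
    """Six-legged body plan with fore/mid/hind anchors along the body axis.

    Anchors sit at ``x = +spacing, 0, -spacing`` (fore, mid, hind) at height
    ``body_height`` above the ground plane y = 0.  Left and right legs share
    anchors in this side-view projection.
    """
    anchor_x = {"F": segment_spacing, "M": 0.0, "H": -segment_spacing}
    return {
        leg: LegChainSpec(leg, (anchor_x[leg[1]], body_height), segment_lengths)
        for leg in LEG_IDS
    }


def _rot(v: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Rotate 2-D vector(s) by ``angle_rad`` (counterclockwise positive)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y = v[..., 0], v[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


#: Bend sense per joint: the leg zigzags — coxa leaves the body axis
#: clockwise (ventral), the femur turns back dorsally, the tibia ventrally.
DEFAULT_BEND_SIGNS = (-1, 1, -1, 1)


def forward_kinematics(
    chain: LegChainSpec,
    joint_angles_deg,
    bend_signs: tuple[int, int, int, int] = DEFAULT_BEND_SIGNS,
) -> np.ndarray:
    """Landmark positions of a leg posed at the given interior joint angles.

    Parameters
    ----------
    chain
        Leg geometry.
    joint_angles_deg
        Array-like of shape ``(..., 4)``: interior angles in degrees at the
        body-coxa, coxa-trochanter, femur-tibia and tibia-tarsus joints, each
        in [0, 180].  The body-coxa angle is measured from the anterior body
        axis.
    bend_signs
        Bend direction at each joint (-1 clockwise, +1 counterclockwise);
        the default alternates, matching the zigzag posture of an insect leg
        in side view.

    Returns
    -------
    ndarray of shape ``(..., 5, 2)`` — the five landmarks from the body-coxa
    joint to the tarsal tip.  Consecutive landmark distances equal the segment
    lengths and the interior angle at each joint equals the input angle.
    """
    ang = np.asarray(joint_angles_deg, dtype=float)
    if ang.shape[-1] != 4:
        raise ValueError("expected 4 joint angles per frame")
    if np.any((ang < 0) | (ang > 180)):
        raise ValueError("joint angles must lie in [0, 180] degrees")
    rad = np.deg2rad(ang)

    base = np.broadcast_to(np.array([1.0, 0.0]), ang.shape[:-1] + (2,))
    points = [np.broadcast_to(np.asarray(chain.anchor, float), base.shape).copy()]
    direction = _rot(base, bend_signs[0] * rad[..., 0])
    points.append(points[-1] + chain.segment_lengths[0] * direction)
    # each later joint turns the chain by the exterior angle (180 - interior)
    for i, length in enumerate(chain.segment_lengths[1:], start=1):
        direction = _rot(direction, bend_signs[i] * (np.pi - rad[..., i]))
        points.append(points[-1] + length * direction)
    return np.stack(points, axis=-2)


def interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at ``b`` between rays b->a and b->c, in degrees [0, 180].

    Returns NaN where either ray degenerates to zero length (coincident
    landmarks).
    """
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(u * v, axis=-1) / denom
    cosang = np.where(denom > 0, cosang, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def angles_from_landmarks(
    landmarks: np.ndarray, body_axis_anterior: np.ndarray | None = None
) -> np.ndarray:
    """Recover the 4 interior joint angles from 5 leg landmarks.

    ``landmarks`` has shape ``(..., 5, 2)``.  The body-coxa angle is measured
    against the anterior body-axis direction ``body_axis_anterior`` (unit not
    required); if omitted, +x is used.  Inverse of :func:`forward_kinematics`
    up to the shared [0, 180] angle range.
    """
    lm = np.asarray(landmarks, float)
    if body_axis_anterior is None:
        body_axis_anterior = np.array([1.0, 0.0])
    anterior_pt = lm[..., 0, :] + np.asarray(body_axis_anterior, float)
    angles = [interior_angle(anterior_pt, lm[..., 0, :], lm[..., 1, :])]
    for j in range(1, 4):
        angles.append(
            interior_angle(lm[..., j - 1, :], lm[..., j, :], lm[..., j + 1, :])
        )
    return np.stack(angles, axis=-1)
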