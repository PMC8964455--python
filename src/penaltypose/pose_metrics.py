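"""Pose-derived penalty variables.

Body orientation of a player is the 2D rotation of an anatomical left-right
(LR) landmark pair -- shoulders, hips, or the hallux / fifth-toe pair of the
support foot -- after projection onto the pitch plane.  The facing vector is
the (right - left) segment rotated +90 deg counter-clockwise, and the angle
is measured counter-clockwise from +x (toward the attacked goal), in
[0, 360).  The side bucket follows the angle: *right* on [0, 90) u [270,
360), *left* on [90, 270); the boundaries 90 and 270 deg therefore fall to
left and right respectively (half-open buckets).

Goalkeeper anticipation (alpha_GK) is the angle in [0, 180] between the
directed neck -> mid-hip body-axis vectors at the two analysed moments
(run-up start and ball contact), computed in field coordinates.  Foot
displacements D_GKL / D_GKR are the metric Euclidean distances travelled by
the projected left / right ankle between the moments.

Each measure carries a confidence: the mean of the landmark confidences that
entered it (for alpha_GK, the neck and mid-hip scores of both frames).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import body25
from .errors import DegeneratePairError, PenaltyPoseError
from .field_geometry import Homography, project_point
from .keypoint_io import DEFAULT_CONFIDENCE_FLOOR, PersonFrame, get_part

_MIN_SEPARATION = 1e-6  # metres; below this an LR pair is degenerate


@dataclass(frozen=True)
class OrientationMeasure:
    """Orientation of one LR pair: angle (deg), side bucket, confidence."""

    angle: float          # degrees in [0, 360)
    side: str             # "right" or "left"
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle < 360.0:
            raise PenaltyPoseError(f"angle {self.angle} outside [0, 360)")


@dataclass(frozen=True)
class AnticipationMeasure:
    """Goalkeeper anticipation bundle; displacement fields are None when the
    corresponding ankle was missing at either moment."""

    alpha_gk: float                 # degrees in [0, 180]
    d_gk_left: float | None         # metres
    d_gk_right: float | None        # metres
    confidence: float               # mean neck/mid-hip confidence, both frames


def side_of_angle(angle_deg: float) -> str:
    """Right on [0, 90) u [270, 360), left on [90, 270)."""
    a = angle_deg % 360.0
    return "right" if (a < 90.0 or a >= 270.0) else "left"


def pair_orientation(
    left_point: Sequence[float],
    right_point: Sequence[float],
    confidences: Sequence[float],
) -> OrientationMeasure:
    """Orientation of an LR landmark pair already projected to field metres.

    The facing vector is (right - left) rotated +90 deg counter-clockwise;
    the returned angle is measured counter-clockwise from the +x axis.
    """
    dx = right_point[0] - left_point[0]
    dy = right_point[1] - left_point[1]
    if math.hypot(dx, dy) <= _MIN_SEPARATION:
        raise DegeneratePairError("left and right points coincide")
    # rotate (dx, dy) by +90 deg: (x, y) -> (-y, x)
    fx, fy = -dy, dx
    angle = math.degrees(math.atan2(fy, fx)) % 360.0
    return OrientationMeasure(
        angle=angle,
        side=side_of_angle(angle),
        confidence=float(sum(confidences) / len(confidences)),
    )


def support_foot_parts(kicking_foot: str) -> tuple[int, int]:
    """(left_point_part, right_point_part) of the support-foot toe pair.

    The support foot is contralateral to the kicking foot, and the hallux is
    treated as the medial point: on a left support foot the big toe is the
    subject's right-side element of the pair, on a right support foot the
    left-side element.
    """
    if kicking_foot == "right":        # support foot = left
        return (body25.L_SMALL_TOE, body25.L_BIG_TOE)
    if kicking_foot == "left":         # support foot = right
        return (body25.R_BIG_TOE, body25.R_SMALL_TOE)
    raise PenaltyPoseError(f"kicking_foot must be 'right' or 'left', got {kicking_foot!r}")


def kicker_orientations(
    frame: PersonFrame,
    h: Homography,
    kicking_foot: str = "right",
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> Mapping[str, OrientationMeasure | None]:
    """Shoulder, hip and support-foot orientations of the penalty taker.

    Each LR pair is projected through ``h`` and passed to
    :func:`pair_orientation`.  A pair with a missing landmark yields None
    for that measure; the others are still returned.
    """
    pairs = {
        "shoulders": (body25.L_SHOULDER, body25.R_SHOULDER),
        "hips": (body25.L_HIP, body25.R_HIP),
        "support_foot": support_foot_parts(kicking_foot),
    }
    out: dict[str, OrientationMeasure | None] = {}
    for name, (left_part, right_part) in pairs.items():
        left = get_part(frame, left_part, confidence_floor)
        right = get_part(frame, right_part, confidence_floor)
        if left is None or right is None:
            out[name] = None
            continue
        out[name] = pair_orientation(
            project_point(h, left.xy),
            project_point(h, right.xy),
            (left.confidence, right.confidence),
        )
    return out


def anticipation_angle(
    neck_1: Sequence[float],
    midhip_1: Sequence[float],
    neck_2: Sequence[float],
    midhip_2: Sequence[float],
    confidences: Sequence[float],
) -> tuple[float, float]:
    """Angle (deg, in [0, 180]) between the directed neck->mid-hip vectors of
    the two moments, plus the mean of the four landmark confidences."""
    v1 = (midhip_1[0] - neck_1[0], midhip_1[1] - neck_1[1])
    v2 = (midhip_2[0] - neck_2[0], midhip_2[1] - neck_2[1])
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 <= _MIN_SEPARATION or n2 <= _MIN_SEPARATION:
        raise DegeneratePairError("neck and mid-hip coincide at one moment")
    cosang = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    alpha = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return alpha, float(sum(confidences) / len(confidences))


def foot_displacements(
    gk_frame_1: PersonFrame,
    gk_frame_2: PersonFrame,
    h: Homography,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> tuple[float | None, float | None]:
    """(d_gk_left, d_gk_right): metres moved by each projected ankle between
    the two moments; None per foot when an ankle is missing at either moment."""

    def one(part: int) -> float | None:
        a = get_part(gk_frame_1, part, confidence_floor)
        b = get_part(gk_frame_2, part, confidence_floor)
        if a is None or b is None:
            return None
        xa, ya = project_point(h, a.xy)
        xb, yb = project_point(h, b.xy)
        return math.hypot(xb - xa, yb - ya)

    return one(body25.L_ANKLE), one(body25.R_ANKLE)


def anticipation_measure(
    gk_frame_1: PersonFrame,
    gk_frame_2: PersonFrame,
    h: Homography,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> AnticipationMeasure:
    """Full goalkeeper anticipation bundle from the two analysed frames.

    The body axis is projected to field coordinates before the angle is
    taken, so camera perspective does not distort it.  Raises
    :class:`DegeneratePairError` when neck or mid-hip is missing at either
    moment (the angle has no fallback); foot displacements degrade to None
    per foot instead.
    """
    points = {}
    for tag, frame in (("1", gk_frame_1), ("2", gk_frame_2)):
        for part, name in ((body25.NECK, "neck"), (body25.MID_HIP, "midhip")):
            lm = get_part(frame, part, confidence_floor)
            if lm is None:
                raise DegeneratePairError(
                    f"goalkeeper {name} missing at moment {tag}"
                )
            points[f"{name}_{tag}"] = lm
    alpha, conf = anticipation_angle(
        project_point(h, points["neck_1"].xy),
        project_point(h, points["midhip_1"].xy),
        project_point(h, points["neck_2"].xy),
        project_point(h, points["midhip_2"].xy),
        [
            points["neck_1"].confidence,
            points["midhip_1"].confidence,
            points["neck_2"].confidence,
            points["midhip_2"].confidence,
        ],
    )
    d_left, d_right = foot_displacements(gk_frame_1, gk_frame_2, h, confidence_floor)
    return AnticipationMeasure(
        alpha_gk=alpha, d_gk_left=d_left, d_gk_right=d_right, confidence=conf
    )


def ball_speed(
    p1: Sequence[float], p2: Sequence[float], frame_gap: int, fps: float
) -> float:
    """Mean ball speed (m/s) between two field points a known frame gap apart."""
    if fps <= 0:
        raise PenaltyPoseError(f"fps must be > 0, got {fps}")
    if frame_gap < 1:
        raise PenaltyPoseError(f"frame_gap must be >= 1, got {frame_gap}")
    dist = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    return dist * fps / frame_gap
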