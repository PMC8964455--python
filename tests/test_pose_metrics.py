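"""Orientation, anticipation and displacement metrics: hand-derived examples
plus the geometric invariances (rotation equivariance, side flips,
moment symmetry)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penaltypose import body25
from penaltypose.errors import DegeneratePairError, PenaltyPoseError
from penaltypose.field_geometry import Homography
from penaltypose.pose_metrics import (
    anticipation_angle,
    ball_speed,
    foot_displacements,
    kicker_orientations,
    pair_orientation,
    side_of_angle,
    support_foot_parts,
)
from tests.conftest import make_person

finite = st.floats(-100, 100, allow_nan=False)


class TestPairOrientation:
    def test_facing_goal(self):
        m = pair_orientation((0, 1), (0, -1), (0.9, 0.9))
        assert m.angle == pytest.approx(0.0, abs=1e-12)
        assert m.side == "right"

    def test_boundary_90_is_left(self):
        m = pair_orientation((-1, 0), (1, 0), (0.9, 0.9))
        assert m.angle == pytest.approx(90.0)
        assert m.side == "left"

    def test_hand_45_degrees(self):
        m = pair_orientation((0, 0), (1, -1), (0.8, 0.6))
        assert m.angle == pytest.approx(45.0)
        assert m.side == "right"
        assert m.confidence == pytest.approx(0.7)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegeneratePairError):
            pair_orientation((1.0, 2.0), (1.0, 2.0), (0.9, 0.9))

    @given(angle=st.floats(0, 360, exclude_max=True), cx=finite, cy=finite)
    @settings(max_examples=100, deadline=None)
    def test_swap_flips_side_and_shifts_180(self, angle, cx, cy):
        # the half-open bucket boundaries (90/270 deg) are a documented tie
        # rule; float rounding makes the flip property undefined right there
        if min(abs(angle - 90.0), abs(angle - 270.0)) < 1e-9:
            angle += 1e-6
        r = math.radians(angle)
        u = (math.sin(r), -math.cos(r))
        left = (cx - u[0], cy - u[1])
        right = (cx + u[0], cy + u[1])
        m = pair_orientation(left, right, (0.9, 0.9))
        swapped = pair_orientation(right, left, (0.9, 0.9))
        assert (swapped.angle - m.angle) % 360.0 == pytest.approx(180.0, abs=1e-6)
        assert {m.side, swapped.side} == {"left", "right"}

    @given(theta=st.floats(-180, 180))
    @settings(max_examples=60, deadline=None)
    def test_rotation_equivariance(self, theta):
        left, right = (0.0, 1.0), (2.0, -1.0)
        base = pair_orientation(left, right, (0.9, 0.9)).angle
        c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        rot = lambda p: (c * p[0] - s * p[1], s * p[0] + c * p[1])
        rotated = pair_orientation(rot(left), rot(right), (0.9, 0.9)).angle
        assert rotated == pytest.approx((base + theta) % 360.0, abs=1e-6)

    def test_side_bucket_boundaries(self):
        assert side_of_angle(0.0) == "right"
        assert side_of_angle(89.999) == "right"
        assert side_of_angle(90.0) == "left"
        assert side_of_angle(269.999) == "left"
        assert side_of_angle(270.0) == "right"


class TestKickerOrientations:
    H = Homography.identity()

    def test_shoulders_angle_and_mean_confidence(self):
        pf = make_person(overrides={
            body25.L_SHOULDER: (10.0, 1.0, 0.9),
            body25.R_SHOULDER: (10.0, -1.0, 0.8),
        })
        out = kicker_orientations(pf, self.H, kicking_foot="right")
        assert out["shoulders"].angle == pytest.approx(0.0, abs=1e-9)
        assert out["shoulders"].side == "right"
        assert out["shoulders"].confidence == pytest.approx(0.85)

    def test_contralateral_support_foot(self):
        assert support_foot_parts("right") == (body25.L_SMALL_TOE, body25.L_BIG_TOE)
        assert support_foot_parts("left") == (body25.R_BIG_TOE, body25.R_SMALL_TOE)

    def test_missing_hip_gives_partial_result(self):
        pf = make_person(missing_parts={body25.R_HIP})
        out = kicker_orientations(pf, self.H, kicking_foot="right")
        assert out["hips"] is None
        assert out["shoulders"] is not None


class TestAnticipationAngle:
    CONF = (0.9, 0.9, 0.9, 0.9)

    def test_identical_segments_zero(self):
        alpha, conf = anticipation_angle((0, 0), (0, 2), (5, 5), (5, 7), self.CONF)
        assert alpha == pytest.approx(0.0, abs=1e-12)
        assert conf == pytest.approx(0.9)

    def test_hand_45_degrees(self):
        # neck->midhip vectors (0,2) and (2,2)
        alpha, _ = anticipation_angle((0, 0), (0, 2), (0, 0), (2, 2), self.CONF)
        assert alpha == pytest.approx(45.0)

    def test_perpendicular_90(self):
        alpha, _ = anticipation_angle((0, 0), (0, 2), (0, 0), (3, 0), self.CONF)
        assert alpha == pytest.approx(90.0)

    def test_degenerate_segment(self):
        with pytest.raises(DegeneratePairError):
            anticipation_angle((1, 1), (1, 1), (0, 0), (0, 1), self.CONF)

    @given(
        scale=st.floats(0.01, 50),
        tx=finite,
        ty=finite,
    )
    @settings(max_examples=60, deadline=None)
    def test_translation_scale_invariance_and_symmetry(self, scale, tx, ty):
        n1, h1, n2, h2 = (0.0, 0.0), (0.5, 1.8), (1.0, 1.0), (2.1, 1.4)
        base, _ = anticipation_angle(n1, h1, n2, h2, self.CONF)
        t = lambda p: (scale * p[0] + tx, scale * p[1] + ty)
        moved, _ = anticipation_angle(t(n1), t(h1), t(n2), t(h2), self.CONF)
        swapped, _ = anticipation_angle(n2, h2, n1, h1, self.CONF)
        assert moved == pytest.approx(base, abs=1e-6)
        assert swapped == pytest.approx(base, abs=1e-9)


class TestFootDisplacements:
    H = Homography.identity()

    def test_stationary_feet(self):
        pf = make_person()
        assert foot_displacements(pf, pf, self.H) == (0.0, 0.0)

    def test_pythagoras(self):
        f1 = make_person(0, overrides={body25.L_ANKLE: (0.0, 0.0, 0.9)})
        f2 = make_person(1, overrides={body25.L_ANKLE: (3.0, 4.0, 0.9)})
        d_left, _ = foot_displacements(f1, f2, self.H)
        assert d_left == pytest.approx(5.0)

    def test_missing_ankle_flags_one_foot(self):
        f1 = make_person(0)
        f2 = make_person(1, missing_parts={body25.R_ANKLE})
        d_left, d_right = foot_displacements(f1, f2, self.H)
        assert d_right is None
        assert d_left is not None

    def test_triangle_inequality_over_three_moments(self, rng):
        frames = [
            make_person(i, overrides={body25.L_ANKLE: (float(x), float(y), 0.9)})
            for i, (x, y) in enumerate(rng.uniform(-5, 5, size=(3, 2)))
        ]
        d01, _ = foot_displacements(frames[0], frames[1], self.H)
        d12, _ = foot_displacements(frames[1], frames[2], self.H)
        d02, _ = foot_displacements(frames[0], frames[2], self.H)
        assert d02 <= d01 + d12 + 1e-12


class TestBallSpeed:
    def test_hand_arithmetic(self):
        assert ball_speed((0, 0), (7, 0), frame_gap=10, fps=25) == pytest.approx(17.5)

    def test_zero_displacement(self):
        assert ball_speed((3, 4), (3, 4), 5, 30.0) == 0.0

    def test_bad_fps_and_gap(self):
        with pytest.raises(PenaltyPoseError):
            ball_speed((0, 0), (1, 0), 1, 0.0)
        with pytest.raises(PenaltyPoseError):
            ball_speed((0, 0), (1, 0), 0, 25.0)
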