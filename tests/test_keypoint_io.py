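"""Keypoint parsing, missing-landmark handling, frame resolution and role
assignment."""

import json

import numpy as np
import pytest

from penaltypose import body25
from penaltypose.errors import (
    FrameResolutionError,
    KeypointFormatError,
    RoleAssignmentError,
)
from penaltypose.field_geometry import Homography
from penaltypose.keypoint_io import (
    Landmark,
    MomentAnnotation,
    Track,
    assign_roles,
    build_tracks,
    get_part,
    read_openpose_frames,
    resolve_frame,
    write_openpose_frames,
)
from tests.conftest import make_person


def write_frame_json(path, frame_index, people_floats, prefix="clip"):
    payload = {"version": 1.3, "people": [{"pose_keypoints_2d": p} for p in people_floats]}
    f = path / f"{prefix}_{frame_index:012d}_keypoints.json"
    f.write_text(json.dumps(payload))
    return f


class TestReadOpenposeFrames:
    def test_single_person_75_floats(self, tmp_path):
        floats = [float(i) for i in range(73)] + [0.5, 0.5]
        # keep confidences legal: every third value in [0, 1]
        floats = []
        for i in range(25):
            floats += [float(i), float(2 * i), 0.9]
        write_frame_json(tmp_path, 0, [floats])
        frames = read_openpose_frames(tmp_path)
        assert len(frames) == 1
        assert len(frames[0].landmarks) == 25
        assert frames[0].landmarks[3] == Landmark(3.0, 6.0, 0.9)

    def test_sentinel_marks_neck_missing(self, tmp_path):
        floats = []
        for i in range(25):
            floats += ([0.0, 0.0, 0.0] if i == body25.NECK else [1.0, 2.0, 0.9])
        write_frame_json(tmp_path, 4, [floats])
        (frame,) = read_openpose_frames(tmp_path)
        assert get_part(frame, body25.NECK) is None
        assert get_part(frame, body25.NOSE) is not None

    def test_wrong_float_count_names_expectation(self, tmp_path):
        write_frame_json(tmp_path, 0, [[1.0] * 74])
        with pytest.raises(KeypointFormatError, match="expected 75 values"):
            read_openpose_frames(tmp_path)

    def test_unreadable_source(self, tmp_path):
        with pytest.raises(OSError):
            read_openpose_frames(tmp_path / "nope")

    def test_roundtrip_is_lossless(self, tmp_path):
        people = [
            make_person(frame_index=f, person_index=p, base=(100.0 * p + 0.125, 7.25 * f))
            for f in range(3)
            for p in range(2)
        ]
        write_openpose_frames(people, tmp_path / "out", prefix="pen")
        back = read_openpose_frames(tmp_path / "out")
        assert back == sorted(people, key=lambda x: (x.frame_index, x.person_index))


class TestGetPart:
    def test_returns_landmark(self):
        pf = make_person(overrides={body25.NECK: (412.0, 220.5, 0.93)})
        assert get_part(pf, body25.NECK) == Landmark(412.0, 220.5, 0.93)

    def test_sentinel_is_missing(self):
        pf = make_person(missing_parts={body25.MID_HIP})
        assert get_part(pf, body25.MID_HIP) is None

    def test_subfloor_confidence_is_missing(self):
        pf = make_person(overrides={body25.NECK: (10.0, 10.0, 0.01)})
        assert get_part(pf, body25.NECK) is None
        assert get_part(pf, body25.NECK, confidence_floor=0.0) is not None

    def test_part_out_of_range(self):
        with pytest.raises(KeypointFormatError):
            get_part(make_person(), 25)


class TestResolveFrame:
    def make_track(self, missing_by_frame):
        frames = [
            make_person(frame_index=f, missing_parts=missing)
            for f, missing in missing_by_frame.items()
        ]
        return Track(frames=frames)

    def test_target_complete_returns_target(self):
        track = self.make_track({9: set(), 10: set(), 11: set()})
        assert resolve_frame(track, 10, {body25.NECK, body25.MID_HIP}, 3) == 10

    def test_nearest_then_earlier(self):
        # target 10 missing Neck; 9 and 12 complete -> 9 (distance 1 beats 2)
        track = self.make_track({9: set(), 10: {body25.NECK}, 11: {body25.NECK}, 12: set()})
        assert resolve_frame(track, 10, {body25.NECK}, 3) == 9

    def test_tie_goes_to_earlier_frame(self):
        track = self.make_track({9: set(), 10: {body25.NECK}, 11: set()})
        assert resolve_frame(track, 10, {body25.NECK}, 3) == 9

    def test_window_exhausted_lists_missing_parts(self):
        track = self.make_track({f: {body25.MID_HIP} for f in range(8, 13)})
        with pytest.raises(FrameResolutionError, match="MidHip"):
            resolve_frame(track, 10, {body25.MID_HIP}, 2)

    def test_zero_offset_returns_target_or_errors(self):
        track = self.make_track({9: set(), 10: {body25.NECK}})
        assert resolve_frame(track, 9, {body25.NECK}, 0) == 9
        with pytest.raises(FrameResolutionError):
            resolve_frame(track, 10, {body25.NECK}, 0)


class TestAssignRoles:
    # identity homography: image coordinates are field metres directly
    H = Homography.identity()

    def test_nearest_goal_line_is_goalkeeper(self):
        gk = make_person(person_index=0, overrides={body25.MID_HIP: (0.8, 0.0, 0.9)})
        kicker = make_person(person_index=1, overrides={body25.MID_HIP: (11.2, 0.0, 0.9)})
        roles = assign_roles([gk, kicker], self.H, goal_line_x=0.0)
        assert roles == {"goalkeeper": 0, "kicker": 1}

    def test_single_person_errors(self):
        only = make_person(overrides={body25.MID_HIP: (1.0, 0.0, 0.9)})
        with pytest.raises(RoleAssignmentError):
            assign_roles([only], self.H)

    def test_equidistant_tie_breaks_to_lower_index(self):
        a = make_person(person_index=2, overrides={body25.MID_HIP: (5.0, 1.0, 0.9)})
        b = make_person(person_index=7, overrides={body25.MID_HIP: (-5.0, 2.0, 0.9)})
        roles = assign_roles([b, a], self.H, goal_line_x=0.0)
        assert roles["goalkeeper"] == 2


class TestTrackBuilding:
    def test_two_actor_linking_by_midhip(self):
        frames = []
        for f in range(5):
            # actor A drifts right, actor B stays; person order flips at frame 3
            a = make_person(f, 0 if f < 3 else 1, overrides={body25.MID_HIP: (100.0 + 10 * f, 50.0, 0.9)})
            b = make_person(f, 1 if f < 3 else 0, overrides={body25.MID_HIP: (500.0, 300.0, 0.9)})
            frames += [a, b]
        tracks = build_tracks(frames, n_tracks=2)
        assert len(tracks) == 2
        xs = [t.frames[-1].landmarks[body25.MID_HIP].x for t in tracks]
        assert sorted(round(x) for x in xs) == [140, 500]
        assert all(len(t.frames) == 5 for t in tracks)

    def test_duplicate_frame_index_rejected(self):
        with pytest.raises(KeypointFormatError):
            Track(frames=[make_person(0), make_person(0)])


def test_moment_annotation_ordering_enforced():
    with pytest.raises(KeypointFormatError):
        MomentAnnotation("p1", runup_start_frame=10, ball_contact_frame=10)
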