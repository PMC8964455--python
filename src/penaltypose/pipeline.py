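"""End-to-end orchestration: extract -> merge -> analyze.

``extract_scene_metrics`` turns one penalty's two tracks plus the field
homography into the per-penalty pose record (orientation angles, sides and
confidences for shoulders / hips / support foot; goalkeeper anticipation
angle, foot displacements and confidence).  Measures whose landmarks cannot
be resolved within the neighbour-frame window degrade to NaN flags rather
than aborting the penalty; infrastructure failures (missing files, degenerate
homography) raise :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import body25
from .errors import (
    DegeneratePairError,
    FrameResolutionError,
    PenaltyPoseError,
    PipelineStageError,
    RoleAssignmentError,
)
from .field_geometry import Homography, estimate_homography, project_point, read_corner_file
from .keypoint_io import (
    DEFAULT_CONFIDENCE_FLOOR,
    MomentAnnotation,
    Track,
    assign_roles,
    build_tracks,
    get_part,
    read_annotations,
    read_openpose_frames,
    resolve_frame,
)
from .pose_metrics import (
    anticipation_angle,
    foot_displacements,
    pair_orientation,
    support_foot_parts,
)

DEFAULT_NEIGHBOR_WINDOW = 5

#: column order of the per-penalty metrics record
METRIC_COLUMNS = (
    "penalty_id",
    "alpha_sh", "lr_sh", "c_sh",
    "alpha_hi", "lr_hi", "c_hi",
    "alpha_sf", "lr_sf", "c_sf",
    "alpha_gk", "c_gk",
    "d_gk_left", "d_gk_right",
)


def _pair_measure(track, target, parts, h, window, floor):
    """Resolve a frame for one LR pair and measure it; NaN-triple on failure."""
    try:
        frame_index = resolve_frame(track, target, parts, window, floor)
    except FrameResolutionError:
        return None
    frame = track.frame_at(frame_index)
    left = get_part(frame, parts[0], floor)
    right = get_part(frame, parts[1], floor)
    try:
        return pair_orientation(
            project_point(h, left.xy),
            project_point(h, right.xy),
            (left.confidence, right.confidence),
        )
    except DegeneratePairError:
        return None


def extract_scene_metrics(
    kicker: Track,
    goalkeeper: Track,
    h: Homography,
    annotation: MomentAnnotation,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> dict:
    """Per-penalty pose record from the two annotated moments.

    Kicker orientations are measured at ball contact (support foot planted);
    goalkeeper anticipation spans run-up start to ball contact.  Each
    measure resolves its own nearest usable frame within the window.
    """
    contact = annotation.ball_contact_frame
    start = annotation.runup_start_frame
    rec: dict = {c: math.nan for c in METRIC_COLUMNS}
    rec["penalty_id"] = annotation.penalty_id
    rec["lr_sh"] = rec["lr_hi"] = rec["lr_sf"] = None

    pairs = {
        "sh": (body25.L_SHOULDER, body25.R_SHOULDER),
        "hi": (body25.L_HIP, body25.R_HIP),
        "sf": support_foot_parts(annotation.kicking_foot),
    }
    for tag, parts in pairs.items():
        m = _pair_measure(kicker, contact, parts, h, neighbor_window, confidence_floor)
        if m is not None:
            rec[f"alpha_{tag}"] = m.angle
            rec[f"lr_{tag}"] = m.side
            rec[f"c_{tag}"] = m.confidence

    axis_parts = (body25.NECK, body25.MID_HIP)
    try:
        f1 = resolve_frame(goalkeeper, start, axis_parts, neighbor_window, confidence_floor)
        f2 = resolve_frame(goalkeeper, contact, axis_parts, neighbor_window, confidence_floor)
    except FrameResolutionError:
        return rec
    gk1 = goalkeeper.frame_at(f1)
    gk2 = goalkeeper.frame_at(f2)
    neck1 = get_part(gk1, body25.NECK, confidence_floor)
    hip1 = get_part(gk1, body25.MID_HIP, confidence_floor)
    neck2 = get_part(gk2, body25.NECK, confidence_floor)
    hip2 = get_part(gk2, body25.MID_HIP, confidence_floor)
    try:
        alpha, conf = anticipation_angle(
            project_point(h, neck1.xy),
            project_point(h, hip1.xy),
            project_point(h, neck2.xy),
            project_point(h, hip2.xy),
            [neck1.confidence, hip1.confidence, neck2.confidence, hip2.confidence],
        )
        rec["alpha_gk"] = alpha
        rec["c_gk"] = conf
    except DegeneratePairError:
        pass
    d_left, d_right = foot_displacements(gk1, gk2, h, confidence_floor)
    rec["d_gk_left"] = math.nan if d_left is None else d_left
    rec["d_gk_right"] = math.nan if d_right is None else d_right
    return rec


def identify_tracks(
    tracks: Sequence[Track],
    h: Homography,
    annotation: MomentAnnotation,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> tuple[Track, Track]:
    """(kicker, goalkeeper) from unlabelled tracks via projected MidHips at
    (or near) ball contact."""
    representatives = []
    for track in tracks:
        try:
            fi = resolve_frame(
                track, annotation.ball_contact_frame, [body25.MID_HIP],
                neighbor_window, confidence_floor,
            )
        except FrameResolutionError:
            continue
        representatives.append((track, track.frame_at(fi)))
    if len(representatives) < 2:
        raise RoleAssignmentError(
            f"penalty {annotation.penalty_id}: fewer than 2 tracks with a "
            "resolvable MidHip near ball contact"
        )
    roles = assign_roles([pf for _, pf in representatives], h,
                         confidence_floor=confidence_floor)
    by_person = {pf.person_index: track for track, pf in representatives}
    return by_person[roles["kicker"]], by_person[roles["goalkeeper"]]


def extract_study(
    keypoints_root: str | Path,
    corners_path: str | Path,
    annotations_path: str | Path,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> pd.DataFrame:
    """Extract the per-penalty metrics table for a whole study directory.

    Layout: ``keypoints_root/<penalty_id>/`` holds that penalty's per-frame
    JSON; one corner file and one annotation table are shared.
    """
    try:
        correspondences = read_corner_file(corners_path)
        h = estimate_homography(correspondences)
    except (OSError, KeyError, PenaltyPoseError) as exc:
        raise PipelineStageError(f"field_geometry stage failed: {exc}") from exc
    try:
        annotations = read_annotations(annotations_path)
    except (OSError, KeyError, ValueError) as exc:
        raise PipelineStageError(f"annotation stage failed: {exc}") from exc

    rows = []
    root = Path(keypoints_root)
    for ann in annotations:
        clip_dir = root / ann.penalty_id
        try:
            frames = read_openpose_frames(clip_dir, dialect="openpose-json")
            tracks = build_tracks(frames, n_tracks=2)
            kicker, goalkeeper = identify_tracks(
                tracks, h, ann, confidence_floor, neighbor_window
            )
        except (OSError, PenaltyPoseError) as exc:
            raise PipelineStageError(
                f"keypoint_io stage failed for penalty {ann.penalty_id}: {exc}"
            ) from exc
        rows.append(
            extract_scene_metrics(
                kicker, goalkeeper, h, ann, confidence_floor, neighbor_window
            )
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def extract_bundle_metrics(
    bundle,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> dict:
    """In-memory extraction for a :class:`~penaltypose.synthetic_scenes.SceneBundle`:
    estimates the homography from the bundle's own corner correspondences and
    measures the scene, without touching disk."""
    h = estimate_homography(bundle.correspondences)
    return extract_scene_metrics(
        bundle.kicker, bundle.goalkeeper, h, bundle.annotation,
        confidence_floor, neighbor_window,
    )
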