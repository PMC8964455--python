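"""Reading, validating and indexing 2D pose-estimator keypoint output.

The unit of input is one 25-landmark BODY_25 skeleton per person per frame,
each landmark an (x, y, confidence) triplet (75 floats per person).  Two
dialects are supported:

``openpose-json``
    One JSON file per frame, named ``<prefix>_<frame:012d>_keypoints.json``,
    with a ``people`` list whose entries carry ``pose_keypoints_2d`` (75
    floats).  The frame index is parsed from the file name.

``csv``
    A consolidated long table with columns
    ``frame, person, part, x, y, conf``.

A landmark with the sentinel triplet (0, 0, 0), or with confidence below the
acceptance floor (default 0.05), is treated as *missing* and never enters
any geometric computation.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import body25
from .errors import (
    FrameResolutionError,
    KeypointFormatError,
    RoleAssignmentError,
)
from .field_geometry import Homography, project_point

#: landmarks scored below this confidence are treated as missing
DEFAULT_CONFIDENCE_FLOOR = 0.05

_FRAME_RE = re.compile(r"_(\d+)_keypoints\.json$")


@dataclass(frozen=True)
class Landmark:
    """One body part in image coordinates (pixels, y downward-positive)."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise KeypointFormatError(
                f"confidence {self.confidence} outside [0, 1]"
            )

    @property
    def is_sentinel(self) -> bool:
        """True for the (0, 0, 0) 'not detected' triplet."""
        return self.x == 0.0 and self.y == 0.0 and self.confidence == 0.0

    def is_missing(self, confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR) -> bool:
        return self.is_sentinel or self.confidence < confidence_floor

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class PersonFrame:
    """One skeleton at one frame: exactly 25 landmarks, BODY_25 order."""

    frame_index: int
    person_index: int
    landmarks: tuple[Landmark, ...]

    def __post_init__(self) -> None:
        if self.frame_index < 0 or self.person_index < 0:
            raise KeypointFormatError("frame/person indices must be >= 0")
        if len(self.landmarks) != body25.N_PARTS:
            raise KeypointFormatError(
                f"frame {self.frame_index} person {self.person_index}: "
                f"expected {body25.N_PARTS} landmarks, got {len(self.landmarks)}"
            )


@dataclass
class Track:
    """Ordered sequence of PersonFrames for one actor."""

    role: str = "unassigned"  # {kicker, goalkeeper, unassigned}
    frames: list[PersonFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = sorted(self.frames, key=lambda f: f.frame_index)
        indices = [f.frame_index for f in self.frames]
        if len(set(indices)) != len(indices):
            raise KeypointFormatError("track holds duplicate frame indices")

    def frame_at(self, frame_index: int) -> PersonFrame | None:
        for f in self.frames:
            if f.frame_index == frame_index:
                return f
        return None

    def append(self, frame: PersonFrame) -> None:
        if self.frame_at(frame.frame_index) is not None:
            raise KeypointFormatError(
                f"track already holds frame {frame.frame_index}"
            )
        self.frames.append(frame)
        self.frames.sort(key=lambda f: f.frame_index)


@dataclass(frozen=True)
class MomentAnnotation:
    """The two analysed moments of one penalty: run-up start and ball contact."""

    penalty_id: str
    runup_start_frame: int
    ball_contact_frame: int
    fps: float = 25.0
    kicking_foot: str = "right"

    def __post_init__(self) -> None:
        if self.runup_start_frame >= self.ball_contact_frame:
            raise KeypointFormatError(
                "runup_start_frame must precede ball_contact_frame"
            )
        if self.kicking_foot not in ("right", "left"):
            raise KeypointFormatError(f"bad kicking_foot {self.kicking_foot!r}")


def _person_from_floats(
    values: Sequence[float], frame_index: int, person_index: int
) -> PersonFrame:
    if len(values) != body25.FLOATS_PER_PERSON:
        raise KeypointFormatError(
            f"frame {frame_index} person {person_index}: expected "
            f"{body25.FLOATS_PER_PERSON} values, got {len(values)}"
        )
    landmarks = tuple(
        Landmark(float(values[3 * i]), float(values[3 * i + 1]), float(values[3 * i + 2]))
        for i in range(body25.N_PARTS)
    )
    return PersonFrame(frame_index, person_index, landmarks)


def read_openpose_frames(
    source: str | Path, dialect: str = "openpose-json"
) -> list[PersonFrame]:
    """Parse keypoint output into PersonFrames, sorted by (frame, person).

    ``source`` is a directory of per-frame JSON files for the
    ``openpose-json`` dialect, or a single CSV file for ``csv``.
    """
    source = Path(source)
    if not source.exists():
        raise OSError(f"keypoint source {source} does not exist")
    if dialect == "openpose-json":
        frames = []
        for path in sorted(source.glob("*_keypoints.json")):
            m = _FRAME_RE.search(path.name)
            if m is None:
                raise KeypointFormatError(
                    f"cannot parse frame index from file name {path.name}"
                )
            frame_index = int(m.group(1))
            payload = json.loads(path.read_text())
            people = payload.get("people", [])
            for person_index, person in enumerate(people):
                frames.append(
                    _person_from_floats(
                        person["pose_keypoints_2d"], frame_index, person_index
                    )
                )
        frames.sort(key=lambda f: (f.frame_index, f.person_index))
        return frames
    if dialect == "csv":
        rows: dict[tuple[int, int], dict[int, Landmark]] = {}
        with source.open(newline="") as fh:
            for rec in csv.DictReader(fh):
                key = (int(rec["frame"]), int(rec["person"]))
                part = int(rec["part"])
                rows.setdefault(key, {})[part] = Landmark(
                    float(rec["x"]), float(rec["y"]), float(rec["conf"])
                )
        frames = []
        for (frame_index, person_index), parts in sorted(rows.items()):
            if sorted(parts) != list(range(body25.N_PARTS)):
                raise KeypointFormatError(
                    f"frame {frame_index} person {person_index}: expected "
                    f"{body25.FLOATS_PER_PERSON} values, got {3 * len(parts)}"
                )
            frames.append(
                PersonFrame(
                    frame_index,
                    person_index,
                    tuple(parts[i] for i in range(body25.N_PARTS)),
                )
            )
        return frames
    raise KeypointFormatError(f"unknown keypoint dialect {dialect!r}")


def write_openpose_frames(
    frames: Iterable[PersonFrame], out_dir: str | Path, prefix: str = "clip"
) -> None:
    """Write PersonFrames back to the per-frame JSON dialect (lossless)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_frame: dict[int, list[PersonFrame]] = {}
    for pf in frames:
        by_frame.setdefault(pf.frame_index, []).append(pf)
    for frame_index, people in sorted(by_frame.items()):
        payload = {
            "version": 1.3,
            "people": [
                {
                    "person_id": [-1],
                    "pose_keypoints_2d": [
                        v
                        for lm in pf.landmarks
                        for v in (lm.x, lm.y, lm.confidence)
                    ],
                }
                for pf in sorted(people, key=lambda p: p.person_index)
            ],
        }
        path = out_dir / f"{prefix}_{frame_index:012d}_keypoints.json"
        path.write_text(json.dumps(payload))


def get_part(
    frame: PersonFrame,
    part: int,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> Landmark | None:
    """Return the landmark at a BODY_25 index, or None if it is missing.

    A landmark is missing when it carries the (0, 0, 0) sentinel or its
    confidence is below ``confidence_floor``.
    """
    if not 0 <= part < body25.N_PARTS:
        raise KeypointFormatError(f"BODY_25 part index {part} out of range 0..24")
    lm = frame.landmarks[part]
    return None if lm.is_missing(confidence_floor) else lm


def build_tracks(frames: Sequence[PersonFrame], n_tracks: int = 2) -> list[Track]:
    """Group PersonFrames into per-actor tracks.

    Persons are linked across frames greedily by nearest MidHip image
    distance to the track's last known MidHip, falling back to stable person
    ordering when MidHip is unavailable.  Adequate for the two-actor scenes
    this package analyses (one kicker, one goalkeeper, no camera cuts).
    """
    by_frame: dict[int, list[PersonFrame]] = {}
    for pf in frames:
        by_frame.setdefault(pf.frame_index, []).append(pf)
    tracks: list[Track] = []

    def midhip(pf: PersonFrame) -> tuple[float, float] | None:
        lm = get_part(pf, body25.MID_HIP)
        return None if lm is None else lm.xy

    for frame_index in sorted(by_frame):
        people = sorted(by_frame[frame_index], key=lambda p: p.person_index)
        unmatched = list(people)
        if tracks:
            # greedy nearest-MidHip assignment to existing tracks
            candidates = []
            for ti, track in enumerate(tracks):
                last = track.frames[-1]
                ref = midhip(last)
                if ref is None:
                    continue
                for pf in people:
                    cur = midhip(pf)
                    if cur is None:
                        continue
                    d = float(np.hypot(cur[0] - ref[0], cur[1] - ref[1]))
                    candidates.append((d, ti, pf))
            used_tracks: set[int] = set()
            used_people: set[int] = set()
            for d, ti, pf in sorted(candidates, key=lambda c: c[0]):
                if ti in used_tracks or id(pf) in used_people:
                    continue
                tracks[ti].append(pf)
                used_tracks.add(ti)
                used_people.add(id(pf))
            unmatched = [pf for pf in people if id(pf) not in used_people]
            # fall back to stable ordering for leftovers
            open_tracks = [
                t for i, t in enumerate(tracks) if i not in used_tracks
            ]
            for track, pf in zip(open_tracks, unmatched):
                track.append(pf)
            unmatched = unmatched[len(open_tracks):]
        for pf in unmatched:
            if len(tracks) < n_tracks:
                tracks.append(Track(frames=[pf]))
    return tracks


def resolve_frame(
    track: Track,
    target: int,
    required_parts: Iterable[int],
    max_offset: int,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> int:
    """Find the frame nearest ``target`` where all required parts are present.

    Searches offsets 0, -1, +1, -2, +2, ... up to ``max_offset``; ties in
    distance go to the earlier frame.  Raises
    :class:`FrameResolutionError` if no frame in the window qualifies,
    listing which parts were missing at the target frame.
    """
    if not track.frames:
        raise FrameResolutionError("track is empty")
    if max_offset < 0:
        raise FrameResolutionError("max_offset must be >= 0")
    required = sorted(set(required_parts))
    for offset in range(max_offset + 1):
        for candidate in ([target] if offset == 0 else [target - offset, target + offset]):
            pf = track.frame_at(candidate)
            if pf is None:
                continue
            if all(get_part(pf, p, confidence_floor) is not None for p in required):
                return candidate
    pf = track.frame_at(target)
    if pf is None:
        detail = f"frame {target} absent from track"
    else:
        missing = [
            body25.PART_NAMES[p]
            for p in required
            if get_part(pf, p, confidence_floor) is None
        ]
        detail = f"parts missing at frame {target}: {', '.join(missing)}"
    raise FrameResolutionError(
        f"no frame within +/-{max_offset} of {target} has all required parts ({detail})"
    )


def assign_roles(
    persons: Sequence[PersonFrame],
    homography: Homography,
    goal_line_x: float = 0.0,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> Mapping[str, int]:
    """Assign kicker/goalkeeper roles from field-projected MidHip positions.

    The person whose projected MidHip lies nearest the goal line (smallest
    |x - goal_line_x| in the field frame) is the goalkeeper; the farthest is
    the kicker.  Equidistant persons tie-break to the lower person_index as
    goalkeeper.  Returns ``{"goalkeeper": person_index, "kicker": person_index}``.
    """
    distances = []
    for pf in persons:
        lm = get_part(pf, body25.MID_HIP, confidence_floor)
        if lm is None:
            continue
        fx, _ = project_point(homography, lm.xy)
        distances.append((abs(fx - goal_line_x), pf.person_index))
    if len(distances) < 2:
        raise RoleAssignmentError(
            f"need >= 2 persons with a visible MidHip, got {len(distances)}"
        )
    distances.sort()  # by distance, then person_index (tie-break)
    return {"goalkeeper": distances[0][1], "kicker": distances[-1][1]}


def read_annotations(path: str | Path) -> list[MomentAnnotation]:
    """Read moment annotations from CSV or JSON.

    Columns/keys: ``penalty_id, runup_start_frame, ball_contact_frame, fps``
    and optionally ``kicking_foot``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = [records]
    else:
        with path.open(newline="") as fh:
            records = list(csv.DictReader(fh))
    out = []
    for rec in records:
        out.append(
            MomentAnnotation(
                penalty_id=str(rec["penalty_id"]),
                runup_start_frame=int(rec["runup_start_frame"]),
                ball_contact_frame=int(rec["ball_contact_frame"]),
                fps=float(rec.get("fps", 25.0)),
                kicking_foot=str(rec.get("kicking_foot", "right")),
            )
        )
    return out


def write_annotations(annotations: Iterable[MomentAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["penalty_id", "runup_start_frame", "ball_contact_frame", "fps", "kicking_foot"]
        )
        for ann in annotations:
            writer.writerow(
                [
                    ann.penalty_id,
                    ann.runup_start_frame,
                    ann.ball_contact_frame,
                    ann.fps,
                    ann.kicking_foot,
                ]
            )
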