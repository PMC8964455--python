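"""Planar image-to-pitch registration.

A broadcast camera viewing a (locally) flat pitch induces a projective map
between image pixels and metric pitch coordinates.  This module estimates the
3x3 homography ``H`` with the normalized direct linear transformation (DLT)
from >= 4 point correspondences -- typically the four pitch corners, whose
image positions may legitimately fall outside the visible frame -- and
projects image points into the field plane:

    [x', y', 1]^T  ~  H [x, y, w]^T        (defined up to scale)

Field frame convention
----------------------
The origin sits at the centre of the attacked goal line; +x points from the
penalty spot toward the goal (the pitch occupies x <= 0) and +y points to the
kicker's left.  A body orientation of 0 degrees then means "facing the
attacked goal".

Default pitch dimensions are 105 x 68 m and can be overridden wherever they
are used.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, PointAtInfinityError

#: default pitch length / width in metres
PITCH_LENGTH = 105.0
PITCH_WIDTH = 68.0

#: distance of the penalty spot from the goal line (metres)
PENALTY_SPOT = 11.0


@dataclass(frozen=True)
class Correspondence:
    """One image <-> field point pair used for homography estimation.

    ``weight`` is the homogeneous coordinate of the image point (w in the
    projective equation); it is 1 for ordinary pixel measurements.
    """

    image_xy: tuple[float, float]
    field_xy: tuple[float, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight == 0:
            raise GeometryError("correspondence has zero homogeneous weight")


@dataclass(frozen=True)
class Homography:
    """A 3x3 projective map, normalized so that h9 = 1 when |h9| > 1e-9
    (otherwise to unit Frobenius norm)."""

    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise GeometryError(f"homography must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise GeometryError("homography entries must be finite")
        if abs(np.linalg.det(m)) < 1e-12 * max(np.linalg.norm(m, "fro"), 1.0) ** 3:
            raise GeometryError("homography matrix is singular")
        if abs(m[2, 2]) > 1e-9:
            m = m / m[2, 2]
        else:
            m = m / np.linalg.norm(m, "fro")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.matrix @ other.matrix)


def _normalizing_similarity(points: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid at origin, mean distance sqrt(2)."""
    centroid = points.mean(axis=0)
    dist = np.linalg.norm(points - centroid, axis=1).mean()
    scale = np.sqrt(2.0) / dist if dist > 0 else 1.0
    return np.array(
        [
            [scale, 0.0, -scale * centroid[0]],
            [0.0, scale, -scale * centroid[1]],
            [0.0, 0.0, 1.0],
        ]
    )


def estimate_homography(correspondences: Sequence[Correspondence]) -> Homography:
    """Estimate the image -> field homography by normalized DLT.

    With exactly 4 correspondences the solution is exact (reprojection error
    at machine precision); with more it is the algebraic least-squares
    solution of the stacked constraint system.  Hartley point normalization
    is always applied for conditioning.

    Raises
    ------
    GeometryError
        If fewer than 4 correspondences are supplied or the configuration is
        degenerate (e.g. collinear field points).
    """
    if len(correspondences) < 4:
        raise GeometryError(
            f"need at least 4 correspondences, got {len(correspondences)}"
        )
    img = np.array(
        [(c.image_xy[0] / c.weight, c.image_xy[1] / c.weight) for c in correspondences]
    )
    fld = np.array([c.field_xy for c in correspondences])

    t_img = _normalizing_similarity(img)
    t_fld = _normalizing_similarity(fld)
    img_n = (t_img @ np.column_stack([img, np.ones(len(img))]).T).T
    fld_n = (t_fld @ np.column_stack([fld, np.ones(len(fld))]).T).T

    rows = []
    for (x, y, _), (xp, yp, _) in zip(img_n, fld_n):
        rows.append([0, 0, 0, -x, -y, -1, yp * x, yp * y, yp])
        rows.append([x, y, 1, 0, 0, 0, -xp * x, -xp * y, -xp])
    a = np.asarray(rows, dtype=float)

    _, s, vt = np.linalg.svd(a)
    # rank-deficiency beyond the 1-dim null space => degenerate configuration
    if s[6] <= 1e-9 * s[0]:
        raise GeometryError("degenerate correspondence configuration (rank-deficient)")
    h_n = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_fld) @ h_n @ t_img
    try:
        return Homography(h)
    except GeometryError as exc:  # singular recovered matrix
        raise GeometryError(f"degenerate correspondence configuration: {exc}") from exc


def project_point(h: Homography, image_point: Sequence[float]) -> tuple[float, float]:
    """Apply the projective map to one point, returning inhomogeneous (x', y').

    Raises :class:`PointAtInfinityError` if the homogeneous weight of the
    result is below 1e-12 in magnitude.
    """
    x, y = float(image_point[0]), float(image_point[1])
    xp, yp, wp = h.matrix @ (x, y, 1.0)
    if abs(wp) < 1e-12:
        raise PointAtInfinityError(f"point ({x}, {y}) maps to infinity")
    return (float(xp / wp), float(yp / wp))


def project_points(h: Homography, image_points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`project_point` on an (n, 2) array."""
    pts = np.asarray(image_points, dtype=float)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ h.matrix.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise PointAtInfinityError("at least one point maps to infinity")
    return hom[:, :2] / w[:, None]


def read_corner_file(path: str | Path) -> list[Correspondence]:
    """Read corner correspondences from a CSV or JSON file.

    CSV columns: ``corner_id, img_x, img_y, field_x, field_y`` (corner_id
    optional).  JSON: a list of objects with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        with path.open(newline="") as fh:
            records = list(csv.DictReader(fh))
    out = []
    for rec in records:
        out.append(
            Correspondence(
                image_xy=(float(rec["img_x"]), float(rec["img_y"])),
                field_xy=(float(rec["field_x"]), float(rec["field_y"])),
            )
        )
    return out


def write_corner_file(correspondences: Iterable[Correspondence], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["corner_id", "img_x", "img_y", "field_x", "field_y"])
        for i, c in enumerate(correspondences):
            writer.writerow(
                [
                    i,
                    repr(float(c.image_xy[0])),
                    repr(float(c.image_xy[1])),
                    repr(float(c.field_xy[0])),
                    repr(float(c.field_xy[1])),
                ]
            )
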