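"""Planar coordinate frames and transforms.

Convention used throughout the package: 0-based pixel indices, a point
``(x, y)`` means ``(column, row)``, and the origin sits at the center of the
top-left pixel.  All registration stages (channel shift, coarse bead stage,
fine gold stage) exchange coordinates through :class:`PointSet` and map
between frames with :class:`Transform2D`.

Reflections are permitted: a grid imaged in the light microscope is routinely
mirrored relative to its EM view.  A reflecting similarity simply carries a
negative determinant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Point2D",
    "PointSet",
    "Transform2D",
    "Correspondence",
    "apply_transform",
    "invert_transform",
    "compose_transforms",
    "identity_transform",
    "similarity_from_params",
    "TRANSFORM_MODELS",
]

#: transform families ordered from most to least restrictive
TRANSFORM_MODELS = ("translation", "rigid", "similarity", "affine")


class Point2D(NamedTuple):
    """A point in pixel units: x along columns, y along rows."""

    x: float
    y: float


def as_xy_array(points: Iterable) -> np.ndarray:
    """Coerce points (Point2D sequence, (N,2) array, ...) to an (N, 2) float array."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        if arr.size != 2:
            raise ValueError(f"expected a 2-vector, got shape {arr.shape}")
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (N, 2) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("points must be finite")
    return arr


@dataclass
class PointSet:
    """Named fiducial coordinates: the currency of every registration step.

    Parameters
    ----------
    points:
        (N, 2) array of (x, y) pixel coordinates.
    frame_id:
        Label of the coordinate frame the points live in (e.g. ``"fm"``,
        ``"montage"``, ``"tomo_projection"``).
    pixel_size_nm:
        Physical pixel size of that frame, nm/px, when known.
    """

    points: np.ndarray
    frame_id: str
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.points = as_xy_array(self.points) if len(np.atleast_1d(self.points)) else np.empty((0, 2))
        if not self.frame_id:
            raise ValueError("frame_id must be non-empty")
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0 when given")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        for x, y in self.points:
            yield Point2D(float(x), float(y))


@dataclass
class Correspondence:
    """A matched pair of landmarks, source frame -> target frame."""

    source: Point2D
    target: Point2D
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.source = Point2D(*map(float, self.source))
        self.target = Point2D(*map(float, self.target))
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class Transform2D:
    """A planar transform ``p -> matrix @ p + offset`` between two pixel frames.

    ``model`` records the family the transform belongs to (translation, rigid,
    similarity, affine); the linear part of a rigid/similarity transform is a
    (scaled) rotation, possibly composed with a reflection.
    """

    model: str
    matrix: np.ndarray
    offset: np.ndarray
    source_frame: str | None = None
    target_frame: str | None = None

    def __post_init__(self) -> None:
        if self.model not in TRANSFORM_MODELS:
            raise ValueError(f"unknown transform model {self.model!r}; expected one of {TRANSFORM_MODELS}")
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.offset))):
            raise ValueError("transform entries must be finite")
        if np.linalg.det(self.matrix) == 0.0:
            raise ValueError("transform matrix is singular")

    # -- algebra ---------------------------------------------------------
    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def is_reflecting(self) -> bool:
        return self.determinant < 0

    @property
    def scale(self) -> float:
        """Isotropic scale factor |det|^(1/2); exact for rigid/similarity."""
        return float(np.sqrt(abs(self.determinant)))

    def apply(self, points) -> np.ndarray:
        """Map an (N, 2) array (or single point) of (x, y) coordinates."""
        arr = as_xy_array(points)
        out = arr @ self.matrix.T + self.offset
        return out[0] if np.asarray(points, dtype=float).ndim == 1 else out

    def apply_point(self, p: Point2D) -> Point2D:
        x, y = self.apply(np.asarray(p, dtype=float))
        return Point2D(float(x), float(y))

    def inverse(self) -> "Transform2D":
        try:
            minv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in __post_init__
            raise ValueError("cannot invert a singular transform") from exc
        return Transform2D(
            model=self.model,
            matrix=minv,
            offset=-minv @ self.offset,
            source_frame=self.target_frame,
            target_frame=self.source_frame,
        )

    def compose(self, other: "Transform2D") -> "Transform2D":
        """Return self ∘ other: first apply ``other``, then ``self``."""
        model = least_restrictive_model(self.model, other.model)
        return Transform2D(
            model=model,
            matrix=self.matrix @ other.matrix,
            offset=self.matrix @ other.offset + self.offset,
            source_frame=other.source_frame,
            target_frame=self.target_frame,
        )

    def __matmul__(self, other: "Transform2D") -> "Transform2D":
        return self.compose(other)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "matrix": [float(v) for v in self.matrix.ravel()],
            "offset": [float(v) for v in self.offset],
            "source_frame": self.source_frame,
            "target_frame": self.target_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transform2D":
        return cls(
            model=d["model"],
            matrix=np.asarray(d["matrix"], dtype=float).reshape(2, 2),
            offset=np.asarray(d["offset"], dtype=float),
            source_frame=d.get("source_frame"),
            target_frame=d.get("target_frame"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Transform2D":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def least_restrictive_model(a: str, b: str) -> str:
    """Least restrictive of two transform families (translation < ... < affine)."""
    return max((a, b), key=TRANSFORM_MODELS.index)


def identity_transform(model: str = "translation", *, source_frame=None, target_frame=None) -> Transform2D:
    return Transform2D(model, np.eye(2), np.zeros(2), source_frame=source_frame, target_frame=target_frame)


def similarity_from_params(
    rotation_deg: float,
    scale: float,
    translation: Sequence[float] = (0.0, 0.0),
    *,
    reflect: bool = False,
    source_frame: str | None = None,
    target_frame: str | None = None,
) -> Transform2D:
    """Build a similarity transform from interpretable parameters.

    The rotation is counter-clockwise in the (x right, y down) pixel frame
    when the image is displayed with row 0 on top; ``reflect`` mirrors x
    before rotating (determinant becomes negative).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    if reflect:
        rot = rot @ np.diag([-1.0, 1.0])
    return Transform2D(
        "similarity",
        scale * rot,
        np.asarray(translation, dtype=float),
        source_frame=source_frame,
        target_frame=target_frame,
    )


# -- functional wrappers (mirror the dataclass methods) ------------------

def apply_transform(t: Transform2D, p) -> Point2D | np.ndarray:
    """Apply ``t`` to a single Point2D (returns Point2D) or an (N,2) array."""
    if isinstance(p, Point2D) or (np.asarray(p, dtype=float).ndim == 1):
        return t.apply_point(Point2D(*np.asarray(p, dtype=float)))
    return t.apply(p)


def invert_transform(t: Transform2D) -> Transform2D:
    return t.inverse()


def compose_transforms(a: Transform2D, b: Transform2D) -> Transform2D:
    """Return a ∘ b (apply b first)."""
    return a.compose(b)
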