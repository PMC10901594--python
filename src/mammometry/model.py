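"""Domain types for frontal-photo breast landmark analysis.

The landmark schema has exactly 30 named roles: two midline points
(sternal notch, umbilicus), two nipples, and a 13-point breast
"footprint" contour per side.  Coordinates are continuous image pixels,
origin at the top-left pixel center, x increasing rightward and y
increasing downward (inferior on an upright frontal photograph).

Side semantics follow clinical convention: ``L``/``R`` are the
*patient's* left and right, so the patient-right breast appears on the
viewer's left half of the image.

Footprint ordering convention: ordinal 1 is the most medial-superior
contour point; ordinals then proceed laterally along the superior
border and return medially along the inferior border (clockwise on the
patient-left breast as displayed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from shapely.geometry import Point as _ShPoint
from shapely.geometry import Polygon as _ShPolygon

FOOTPRINT_POINTS_PER_SIDE = 13


class Side(str, Enum):
    LEFT = "L"
    RIGHT = "R"


_FOOTPRINT_L = tuple(f"FOOTPRINT_L_{i:02d}" for i in range(1, FOOTPRINT_POINTS_PER_SIDE + 1))
_FOOTPRINT_R = tuple(f"FOOTPRINT_R_{i:02d}" for i in range(1, FOOTPRINT_POINTS_PER_SIDE + 1))
_ALL_ROLE_NAMES = ("STERNAL_NOTCH", "UMBILICUS", "NIPPLE_L", "NIPPLE_R") + _FOOTPRINT_L + _FOOTPRINT_R

LandmarkRole = Enum("LandmarkRole", {name: name for name in _ALL_ROLE_NAMES}, type=str)
LandmarkRole.__doc__ = "The 30 landmark roles of the frontal-photo schema."

#: Canonical role ordering used for serialization and array layouts.
ROLE_ORDER: tuple = tuple(LandmarkRole)

NIPPLE = {Side.LEFT: LandmarkRole.NIPPLE_L, Side.RIGHT: LandmarkRole.NIPPLE_R}
FOOTPRINT_ROLES = {
    Side.LEFT: tuple(LandmarkRole[n] for n in _FOOTPRINT_L),
    Side.RIGHT: tuple(LandmarkRole[n] for n in _FOOTPRINT_R),
}


def role_side(role: "LandmarkRole") -> Side | None:
    """Side tag of a role, or None for midline roles."""
    if role.name.endswith("_L") or "_L_" in role.name:
        return Side.LEFT
    if role.name.endswith("_R") or "_R_" in role.name:
        return Side.RIGHT
    return None


def footprint_ordinal(role: "LandmarkRole") -> int | None:
    """1-based ordinal of a footprint role, or None for non-footprint roles."""
    if role.name.startswith("FOOTPRINT_"):
        return int(role.name.rsplit("_", 1)[1])
    return None


@dataclass(frozen=True)
class LandmarkPoint:
    role: LandmarkRole
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate for {self.role.name}: ({self.x}, {self.y})")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


class SchemaError(ValueError):
    """A landmark annotation violates the 30-role schema."""


@dataclass
class LandmarkSet:
    """One complete 30-point annotation, optionally tied to an image.

    ``points`` is keyed by role; construction rejects duplicate or
    missing roles (use :class:`SchemaError` handling at I/O boundaries).
    """

    points: dict
    image_width: int | None = None
    image_height: int | None = None
    metadata: dict = field(default_factory=dict)

    def __init__(self, points, image_width=None, image_height=None, metadata=None):
        mapping: dict = {}
        for p in points.values() if isinstance(points, dict) else points:
            if p.role in mapping:
                raise SchemaError(f"duplicate role: {p.role.name}")
            mapping[p.role] = p
        missing = [r.name for r in ROLE_ORDER if r not in mapping]
        if missing:
            raise SchemaError(f"missing role: {missing[0]}" if len(missing) == 1
                              else "missing roles: " + ", ".join(missing))
        self.points = {r: mapping[r] for r in ROLE_ORDER}
        self.image_width = image_width
        self.image_height = image_height
        self.metadata = dict(metadata or {})

    def __getitem__(self, role: LandmarkRole) -> LandmarkPoint:
        return self.points[role]

    def xy(self, role: LandmarkRole) -> np.ndarray:
        return self.points[role].xy

    def footprint(self, side: Side) -> np.ndarray:
        """(13, 2) footprint vertex array in ordinal order."""
        return np.array([self.points[r].xy for r in FOOTPRINT_ROLES[side]])

    def as_array(self) -> np.ndarray:
        """(30, 2) coordinate array in canonical role order."""
        return np.array([self.points[r].xy for r in ROLE_ORDER])

    def replace_coordinates(self, coords: np.ndarray) -> "LandmarkSet":
        """New set with coordinates taken from a (30, 2) array in canonical order."""
        coords = np.asarray(coords, dtype=float)
        pts = [LandmarkPoint(r, float(coords[i, 0]), float(coords[i, 1]))
               for i, r in enumerate(ROLE_ORDER)]
        return LandmarkSet(pts, self.image_width, self.image_height, dict(self.metadata))


@dataclass
class ImageRecord:
    """In-memory raster image: 2-D grayscale or (H, W, 3) RGB, 8- or 16-bit."""

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.ndim not in (2, 3) or (self.pixels.ndim == 3 and self.pixels.shape[2] != 3):
            raise ValueError(f"pixels must be (H, W) or (H, W, 3), got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image dimensions must be positive")
        vmax = (1 << self.bit_depth) - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > vmax):
            raise ValueError(f"pixel values outside [0, {vmax}] for bit depth {self.bit_depth}")

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass(frozen=True)
class AffineTransform2D:
    """2x3 affine map from source to target pixel coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine transform is not invertible")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]]))

    @classmethod
    def scaling(cls, s: float, tx: float = 0.0, ty: float = 0.0) -> "AffineTransform2D":
        return cls(np.array([[s, 0.0, tx], [0.0, s, ty]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform2D":
        a = self.matrix[:, :2]
        inv = np.linalg.inv(a)
        t = -inv @ self.matrix[:, 2]
        return AffineTransform2D(np.column_stack([inv, t]))

    def compose(self, inner: "AffineTransform2D") -> "AffineTransform2D":
        """Transform equal to applying ``inner`` first, then ``self``."""
        a = self.matrix[:, :2] @ inner.matrix[:, :2]
        t = self.matrix[:, :2] @ inner.matrix[:, 2] + self.matrix[:, 2]
        return AffineTransform2D(np.column_stack([a, t]))


def _ring_is_simple(vertices: np.ndarray) -> bool:
    ring = _ShPolygon(np.asarray(vertices, dtype=float))
    return bool(ring.is_valid)


def validate_landmark_set(lset: LandmarkSet) -> list:
    """Check every schema invariant; return violation strings (empty = valid).

    Violations are reported as data rather than raised, so callers can
    collect all problems of an annotation at once.
    """
    violations: list = []
    for role, p in lset.points.items():
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            violations.append(f"non-finite coordinate: {role.name}")
        elif lset.image_width is not None and lset.image_height is not None:
            if not (0.0 <= p.x <= lset.image_width - 1 and 0.0 <= p.y <= lset.image_height - 1):
                violations.append(f"out of image bounds: {role.name}")
    for side in Side:
        fp = lset.footprint(side)
        if not _ring_is_simple(fp):
            violations.append(f"self-intersection: FOOTPRINT_{side.value}")
            continue
        poly = _ShPolygon(fp)
        nip = _ShPoint(lset.xy(NIPPLE[side]))
        if not (poly.covers(nip) or poly.exterior.distance(nip) < 1e-9):
            violations.append(f"nipple outside footprint: {side.value}")
    return violations
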