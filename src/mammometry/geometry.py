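"""Planar geometry substrate: midline, reflection, polygon measures.

All routines work in raster coordinates (x rightward, y downward).  A
polygon is an ordered vertex ring, implicitly closed; orientation is
normalized at construction so that downstream measures are
orientation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

from .model import LandmarkRole, LandmarkSet


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Line2D:
    """Line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise GeometryError("degenerate line direction")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal; for an inferior-pointing axis it points patient-left."""
        d = self.direction
        return np.array([d[1], -d[0]])


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Polygon2D:
    """Simple polygon; orientation normalized counter-clockwise in (x, -y)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError(f"polygon needs >= 3 (x, y) vertices, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise GeometryError("non-finite polygon vertex")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if not _ShPolygon(v).is_valid:
            raise GeometryError("polygon is self-intersecting or degenerate")
        # CCW in (x, -y) terms == negative shoelace sign in raster (y-down) coords
        if _signed_area(v) > 0:
            v = v[::-1]
        object.__setattr__(self, "vertices", v)

    def shapely(self) -> _ShPolygon:
        return _ShPolygon(self.vertices)


def estimate_midline(lset: LandmarkSet) -> Line2D:
    """Torso midline: the line through sternal notch and umbilicus.

    Direction is oriented inferiorly (increasing y on an upright photo),
    which makes downstream frames and indices rotate with the patient
    rather than the camera.
    """
    sn = lset.xy(LandmarkRole.STERNAL_NOTCH)
    um = lset.xy(LandmarkRole.UMBILICUS)
    d = um - sn
    if np.linalg.norm(d) < 1e-9:
        raise GeometryError("degenerate midline: sternal notch and umbilicus coincide")
    if d[1] < 0:
        d = -d
    return Line2D(sn, d)


def reflect(points: np.ndarray, axis: Line2D) -> np.ndarray:
    """Householder reflection of points across a line (an involution)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = axis.direction
    house = 2.0 * np.outer(d, d) - np.eye(2)
    out = (pts - axis.point) @ house.T + axis.point
    return out if np.asarray(points).ndim == 2 else out[0]


def polygon_area(p: Polygon2D) -> float:
    """Shoelace area, absolute value, in px^2."""
    return abs(_signed_area(p.vertices))


def polygon_perimeter(p: Polygon2D) -> float:
    """Closed-loop edge length sum, in px."""
    v = p.vertices
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def polygon_intersection_area(a: Polygon2D, b: Polygon2D) -> float:
    """Area of the boolean intersection a ∩ b, in px^2."""
    inter = a.shapely().intersection(b.shapely())
    return float(inter.area)


def lowest_contour_point(p: Polygon2D, direction: np.ndarray | None = None) -> np.ndarray:
    """Contour point extremal along ``direction`` (default image +y).

    With the default direction this is the inferior-most visible point
    of the contour, the frontal-photo stand-in for the inframammary
    fold.  Ties are broken by smaller x.
    """
    d = np.array([0.0, 1.0]) if direction is None else np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    v = p.vertices
    proj = v @ d
    top = proj >= proj.max() - 1e-12
    cands = v[top]
    return cands[np.argmin(cands[:, 0])].copy()


def extent_perpendicular_to(p: Polygon2D, axis: Line2D) -> float:
    """Width of the vertex projection onto the axis normal (max - min)."""
    proj = p.vertices @ axis.normal
    return float(proj.max() - proj.min())
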