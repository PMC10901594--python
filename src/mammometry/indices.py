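"""The seven photometric breast asymmetry indices.

All indices are computed in a midline-anchored frame: u is the signed
perpendicular distance from the torso midline (positive on the
patient's left), v the signed distance along the midline from the
sternal notch (positive inferiorly).  With nipples at (uL, vL) and
(uR, vR) and footprints FL, FR (FR' = FR reflected across the midline):

    BRA = sqrt((|uL| - |uR|)^2 + (vL - vR)^2)   breast retraction assessment
    UNR = |vL - vR|                             upward nipple retraction
    LBC = |arcL - arcR|                         lower breast contour
    BCE = |(vlowL - vL) - (vlowR - vR)|         breast compliance evaluation
    BCD = |perim(FL) - perim(FR)|               breast contour difference
    BAD = |area(FL) - area(FR)|                 breast area difference
    BOD = area(FL) + area(FR') - 2 area(FL∩FR') breast overlap difference

where arc is the polyline length of the inferior footprint border
(ordinal stations 7..13 of the schema ordering, the lateral-to-medial
inferior sweep) and vlow is the v coordinate of the inferior-most
footprint point.  These are the classical
photometric definitions; each formula lives only here so an alternate
convention can be swapped in one place.

Each index is reported three ways: in pixels, in cm/cm^2 (when a
calibration is available), and dimensionless.  Lengths are normalized
by the mean of the two sternal-notch-to-nipple pixel distances, areas
by the larger footprint area, making the dimensionless values invariant
to uniform scaling and hence usable without any physical calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon as _raster_polygon

from .calibration import Calibration
from .geometry import (
    Polygon2D,
    estimate_midline,
    polygon_area,
    polygon_intersection_area,
    polygon_perimeter,
    reflect,
)
from .model import NIPPLE, LandmarkRole, LandmarkSet, Side

LENGTH_INDICES = ("bra", "lbc", "unr", "bce", "bcd")
AREA_INDICES = ("bad", "bod")


class CalibrationUnavailable(RuntimeError):
    """A dimensional (cm) value was requested without a calibration."""


def midline_frame(lset: LandmarkSet) -> dict:
    """Per-role (u, v) coordinates in the midline frame.

    u: signed distance from the midline, positive on the patient-left
    side; v: signed distance along the midline from the sternal notch,
    positive inferiorly.  The frame rotates with the landmark set, so
    everything downstream is invariant to camera roll.
    """
    midline = estimate_midline(lset)
    sn = midline.point
    d, n = midline.direction, midline.normal
    out = {}
    for role, p in lset.points.items():
        rel = p.xy - sn
        out[role] = (float(rel @ n), float(rel @ d))
    return out


def _frame_uv(points: np.ndarray, lset: LandmarkSet) -> np.ndarray:
    midline = estimate_midline(lset)
    rel = np.atleast_2d(points) - midline.point
    return np.column_stack([rel @ midline.normal, rel @ midline.direction])


#: Inferior footprint border: ordinal stations 7..13 of the schema ordering
#: (ordinal 1 is medial-superior and ordinals run laterally along the superior
#: border, so the second half of the ring is the lateral-to-medial inferior
#: sweep).  Fixing the border by ordinals rather than by coordinate extremes
#: keeps the arc a continuous function of the vertex positions.
LOWER_ARC_ORDINALS = tuple(range(7, 14))


def lower_contour_arc(lset: LandmarkSet, side: Side) -> float:
    """Polyline length (px) of the inferior footprint border.

    The border is the lateral-to-medial inferior sweep of the contour,
    stations 7 through 13 in the schema's ordinal ordering.
    """
    fp = lset.footprint(side)
    pts = fp[[o - 1 for o in LOWER_ARC_ORDINALS]]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass(frozen=True)
class IndexValue:
    """One asymmetry index: pixel value, dimensionless value, optional cm value."""

    px: float
    dimensionless: float
    physical: float | None  # cm for lengths, cm^2 for areas

    def require_physical(self) -> float:
        if self.physical is None:
            raise CalibrationUnavailable(
                "dimensional value unavailable: no calibration was supplied")
        return self.physical


@dataclass(frozen=True)
class AsymmetryReport:
    bra: IndexValue
    lbc: IndexValue
    unr: IndexValue
    bce: IndexValue
    bcd: IndexValue
    bad: IndexValue
    bod: IndexValue
    reference_length_px: float
    reference_area_px2: float

    def __getitem__(self, name: str) -> IndexValue:
        return getattr(self, name.lower())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in LENGTH_INDICES + AREA_INDICES:
            iv = self[name]
            rows.append({
                "index": name.upper(),
                "dimensional_value": iv.physical,
                "units": "cm" if name in LENGTH_INDICES else "cm^2",
                "dimensionless_value": iv.dimensionless,
                "pixel_value": iv.px,
            })
        return pd.DataFrame(rows)


def compute_indices(lset: LandmarkSet, cal: Calibration | None = None) -> AsymmetryReport:
    """Compute the seven asymmetry indices for one landmark set.

    With ``cal`` absent only the pixel and dimensionless values are
    populated; requesting a cm value then raises
    :class:`CalibrationUnavailable` rather than silently reading zero.
    """
    midline = estimate_midline(lset)
    frame = midline_frame(lset)

    uL, vL = frame[LandmarkRole.NIPPLE_L]
    uR, vR = frame[LandmarkRole.NIPPLE_R]

    fpL = lset.footprint(Side.LEFT)
    fpR = lset.footprint(Side.RIGHT)
    polyL, polyR = Polygon2D(fpL), Polygon2D(fpR)
    polyR_refl = Polygon2D(reflect(fpR, midline))

    areaL, areaR = polygon_area(polyL), polygon_area(polyR)

    bra = float(np.hypot(abs(uL) - abs(uR), vL - vR))
    unr = float(abs(vL - vR))
    lbc = abs(lower_contour_arc(lset, Side.LEFT) - lower_contour_arc(lset, Side.RIGHT))

    uvL = _frame_uv(fpL, lset)
    uvR = _frame_uv(fpR, lset)
    bce = abs((uvL[:, 1].max() - vL) - (uvR[:, 1].max() - vR))

    bcd = abs(polygon_perimeter(polyL) - polygon_perimeter(polyR))
    bad = abs(areaL - areaR)
    inter = polygon_intersection_area(polyL, polyR_refl)
    bod = max(0.0, areaL + polygon_area(polyR_refl) - 2.0 * inter)

    sn = lset.xy(LandmarkRole.STERNAL_NOTCH)
    ref_len = 0.5 * (np.linalg.norm(lset.xy(LandmarkRole.NIPPLE_L) - sn)
                     + np.linalg.norm(lset.xy(LandmarkRole.NIPPLE_R) - sn))
    ref_area = max(areaL, areaR)

    k = cal.cm_per_px if cal is not None else None

    def length(px: float) -> IndexValue:
        return IndexValue(px, px / ref_len, px * k if k is not None else None)

    def area(px2: float) -> IndexValue:
        return IndexValue(px2, px2 / ref_area, px2 * k * k if k is not None else None)

    return AsymmetryReport(
        bra=length(bra), lbc=length(lbc), unr=length(unr), bce=length(bce),
        bcd=length(bcd), bad=area(bad), bod=area(bod),
        reference_length_px=float(ref_len), reference_area_px2=float(ref_area),
    )


# Flat colors for the overlap rendering (kept exact so painted-region
# pixel counts remain checkable against the polygon BOD).
OVERLAP_COLORS = {
    "background": (24, 24, 28),
    "overlap": (235, 146, 52),    # footprint agreement (orange)
    "difference": (62, 112, 221),  # symmetric difference (blue)
    "nipple": (214, 64, 160),
}


def render_overlap(lset: LandmarkSet, out_path, supersample: int = 4) -> dict:
    """Write the footprint-overlap PNG (reflected right over left).

    The patient-right footprint is mirrored across the midline onto the
    left; the agreement region and the symmetric-difference region get
    distinct flat colors and both nipples (left, and right-reflected)
    are marked.  Rendering is supersampled so the painted
    difference-region pixel count closely tracks the polygon BOD.

    Returns a small summary dict (canvas size, painted pixel counts,
    implied difference area in source px^2).
    """
    midline = estimate_midline(lset)
    fpL = lset.footprint(Side.LEFT)
    fpR_refl = reflect(lset.footprint(Side.RIGHT), midline)

    allpts = np.vstack([fpL, fpR_refl])
    lo = np.floor(allpts.min(axis=0)) - 8
    hi = np.ceil(allpts.max(axis=0)) + 8
    size = ((hi - lo) * supersample).astype(int)  # (w, h)

    def to_canvas(pts):
        return (pts - lo) * supersample

    h, w = int(size[1]), int(size[0])
    maskL = np.zeros((h, w), dtype=bool)
    maskR = np.zeros((h, w), dtype=bool)
    for mask, pts in ((maskL, to_canvas(fpL)), (maskR, to_canvas(fpR_refl))):
        rr, cc = _raster_polygon(pts[:, 1], pts[:, 0], shape=(h, w))
        mask[rr, cc] = True

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = OVERLAP_COLORS["background"]
    both = maskL & maskR
    diff = maskL ^ maskR
    img[both] = OVERLAP_COLORS["overlap"]
    img[diff] = OVERLAP_COLORS["difference"]

    yy, xx = np.mgrid[0:h, 0:w]
    for nip in (lset.xy(NIPPLE[Side.LEFT]), reflect(lset.xy(NIPPLE[Side.RIGHT]), midline)):
        cx, cy = to_canvas(nip[None, :])[0]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= (1.2 * supersample) ** 2
        img[disk] = OVERLAP_COLORS["nipple"]

    Image.fromarray(img).save(out_path)
    return {
        "canvas_size": (w, h),
        "supersample": supersample,
        "difference_pixels": int(diff.sum()),
        "overlap_pixels": int(both.sum()),
        "difference_area_px2": float(diff.sum()) / supersample ** 2,
    }
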