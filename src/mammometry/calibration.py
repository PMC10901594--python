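"""Pixel-to-centimeter calibration and the four clinical distances.

A frontal photograph carries no physical scale, so the user supplies at
least one anchor distance measured on the patient: sternal notch to
right nipple, sternal notch to left nipple, or nipple to nipple.  The
scale is cm_per_px = anchor_cm / anchor_px.  When several anchors are
given, a fixed precedence (SN-to-right-nipple first) selects one rather
than averaging, mirroring the usual validation protocol in which the
right-sided anchor is the one recorded.

Clinical distances per side (all converted to cm):

* SN-N  — sternal notch to nipple (straight-line).
* N-S   — nipple to sternum, taken as the perpendicular distance from
  the nipple to the torso midline.
* N-IMF — nipple to the inferior-most footprint point, the 2-D proxy a
  frontal photo can offer for the nipple-to-inframammary-fold tape
  measurement.  On a ptotic breast the true tape length runs over the
  lower pole and exceeds this projected chord; the proxy is therefore
  expected to under-read, which is exactly the bias the agreement
  statistics quantify.
* BBW   — breast base width, the footprint extent perpendicular to the
  midline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import (
    Line2D,
    Polygon2D,
    estimate_midline,
    extent_perpendicular_to,
    lowest_contour_point,
)
from .model import NIPPLE, LandmarkRole, LandmarkSet, Side


class AnchorKind(str, Enum):
    SN_TO_NIPPLE_R = "SN_TO_NIPPLE_R"
    SN_TO_NIPPLE_L = "SN_TO_NIPPLE_L"
    NIPPLE_TO_NIPPLE = "NIPPLE_TO_NIPPLE"


_ANCHOR_ENDPOINTS = {
    AnchorKind.SN_TO_NIPPLE_R: (LandmarkRole.STERNAL_NOTCH, LandmarkRole.NIPPLE_R),
    AnchorKind.SN_TO_NIPPLE_L: (LandmarkRole.STERNAL_NOTCH, LandmarkRole.NIPPLE_L),
    AnchorKind.NIPPLE_TO_NIPPLE: (LandmarkRole.NIPPLE_R, LandmarkRole.NIPPLE_L),
}

#: Selection order when several anchors are supplied.
ANCHOR_PRECEDENCE = (
    AnchorKind.SN_TO_NIPPLE_R,
    AnchorKind.SN_TO_NIPPLE_L,
    AnchorKind.NIPPLE_TO_NIPPLE,
)


@dataclass(frozen=True)
class CalibrationAnchor:
    kind: AnchorKind
    length_cm: float

    def __post_init__(self) -> None:
        if not (0.0 < self.length_cm < 100.0):
            raise ValueError(f"anchor length must be in (0, 100) cm, got {self.length_cm}")


@dataclass(frozen=True)
class Calibration:
    cm_per_px: float
    anchor_used: CalibrationAnchor

    def __post_init__(self) -> None:
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be positive")


def calibrate(lset: LandmarkSet, anchors) -> Calibration:
    """Derive the cm/px scale from the highest-precedence anchor."""
    if isinstance(anchors, CalibrationAnchor):
        anchors = [anchors]
    anchors = list(anchors)
    if not anchors:
        raise ValueError("at least one calibration anchor is required")
    by_kind = {}
    for a in anchors:
        by_kind.setdefault(a.kind, a)
    anchor = next(by_kind[k] for k in ANCHOR_PRECEDENCE if k in by_kind)
    ra, rb = _ANCHOR_ENDPOINTS[anchor.kind]
    px = float(np.linalg.norm(lset.xy(ra) - lset.xy(rb)))
    if px < 1e-9:
        raise ValueError(f"degenerate anchor: {ra.name} and {rb.name} coincide")
    return Calibration(anchor.length_cm / px, anchor)


def measure(lset: LandmarkSet, cal: Calibration, point_a, point_b) -> float:
    """Distance in cm between two landmarks (by role) or raw (x, y) points."""

    def resolve(p):
        if isinstance(p, LandmarkRole):
            return lset.xy(p)
        if isinstance(p, str):
            try:
                return lset.xy(LandmarkRole[p])
            except KeyError:
                raise ValueError(f"unknown landmark role: {p}") from None
        return np.asarray(p, dtype=float)

    return float(np.linalg.norm(resolve(point_a) - resolve(point_b))) * cal.cm_per_px


@dataclass(frozen=True)
class SidePair:
    left: float
    right: float

    def get(self, side: Side) -> float:
        return self.left if side is Side.LEFT else self.right


@dataclass(frozen=True)
class MeasurementSet:
    """The four clinical distances per side, in cm."""

    sn_to_nipple: SidePair
    nipple_to_sternum: SidePair
    nipple_to_imf: SidePair
    breast_base_width: SidePair

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, pair in (("sn_to_nipple", self.sn_to_nipple),
                           ("nipple_to_sternum", self.nipple_to_sternum),
                           ("nipple_to_imf", self.nipple_to_imf),
                           ("breast_base_width", self.breast_base_width)):
            rows.append({"measure": name, "side": "L", "value_cm": pair.left})
            rows.append({"measure": name, "side": "R", "value_cm": pair.right})
        return pd.DataFrame(rows, columns=["measure", "side", "value_cm"])


def clinical_measurements(lset: LandmarkSet, cal: Calibration,
                          midline: Line2D | None = None) -> MeasurementSet:
    """Compute the four distances per side, in cm.

    The inferior-most footprint point for N-IMF is taken along the
    midline direction (not the image y axis) so the measurement set is
    invariant to how the patient happens to be rotated in the frame.
    """
    midline = midline or estimate_midline(lset)
    sn = lset.xy(LandmarkRole.STERNAL_NOTCH)
    k = cal.cm_per_px

    vals = {}
    for side in Side:
        nip = lset.xy(NIPPLE[side])
        fp = Polygon2D(lset.footprint(side))
        sn_n = np.linalg.norm(nip - sn)
        n_s = abs(float((nip - midline.point) @ midline.normal))
        imf = lowest_contour_point(fp, direction=midline.direction)
        n_imf = np.linalg.norm(nip - imf)
        bbw = extent_perpendicular_to(fp, midline)
        vals[side] = (sn_n * k, n_s * k, n_imf * k, bbw * k)

    return MeasurementSet(
        sn_to_nipple=SidePair(vals[Side.LEFT][0], vals[Side.RIGHT][0]),
        nipple_to_sternum=SidePair(vals[Side.LEFT][1], vals[Side.RIGHT][1]),
        nipple_to_imf=SidePair(vals[Side.LEFT][2], vals[Side.RIGHT][2]),
        breast_base_width=SidePair(vals[Side.LEFT][3], vals[Side.RIGHT][3]),
    )
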