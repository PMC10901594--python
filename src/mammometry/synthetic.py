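"""Seeded synthetic frontal-torso generator with analytic ground truth.

Each sample is a rendered grayscale torso (body ellipse, two shaded
breast mounds, nipple disks, Gaussian pixel noise) plus the exact
30-point landmark set and closed-form reference values for every
clinical distance and asymmetry index.  The generator is the oracle for
the rest of the package: measurements recomputed from the landmark set
must reproduce the analytic values.

Breast footprints are superellipses
``(|x|/a)^n + (|y|/b)^n = 1`` (convex for n >= 2), with an independent
inferior semi-axis ``b + ptosis_drop`` so drooping elongates the lower
pole.  The 13 footprint landmarks are sampled at fixed parameter
angles chosen so ordinal 1 is the medial-superior station and ordinals
run laterally along the superior border then back along the inferior
border, matching the schema convention.

Asymmetry controls: a left-nipple displacement vector, a left/right
footprint area ratio, and the ptosis drop.  The physical scale
``cm_per_px`` defaults to 53.76/width, placing the sternal-notch-to-
nipple distance near 21 cm — the magnitude reported for adult patients
— independent of raster size.

The "true tape" lower-pole length emulates what a flexible tape
measures over the breast mound: the frontal chord from nipple to the
inferior-most footprint point is inflated by arc length over a
half-sine protrusion profile whose depth grows with the ptosis drop.
A frontal photograph can only see the chord, so the photo N-IMF proxy
systematically under-reads this true length — the bias the agreement
statistics are designed to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import AnchorKind, Calibration, CalibrationAnchor, MeasurementSet, SidePair
from .indices import AsymmetryReport, IndexValue
from .model import (
    FOOTPRINT_POINTS_PER_SIDE,
    FOOTPRINT_ROLES,
    NIPPLE,
    ImageRecord,
    LandmarkPoint,
    LandmarkRole,
    LandmarkSet,
    Side,
)

_REF_SIZE = 256.0


@dataclass(frozen=True)
class TorsoParams:
    """Geometric and photometric parameters of one synthetic torso.

    Lengths are in pixels of the requested raster.  Fields left at None
    are resolved to defaults proportional to the image size.
    """

    width: int = 256
    height: int = 256
    midline_x: float | None = None
    tilt_deg: float = 0.0
    sternal_notch_y: float | None = None
    umbilicus_y: float | None = None
    breast_center_y: float | None = None
    breast_offset_x: float | None = None
    semi_axis_a: float | None = None
    semi_axis_b: float | None = None
    exponent: float = 2.5
    rotation_deg_left: float = 0.0
    rotation_deg_right: float = 0.0
    nipple_offset: tuple | None = None
    nipple_displacement: tuple = (0.0, 0.0)
    area_ratio: float = 1.0
    ptosis_drop: float = 0.0
    noise_sigma: float = 4.0
    cm_per_px: float | None = None
    seed: int = 0

    def resolved(self) -> "TorsoParams":
        w, h = self.width, self.height
        def default(cur, val):
            return val if cur is None else cur
        out = replace(
            self,
            midline_x=default(self.midline_x, w / 2.0),
            sternal_notch_y=default(self.sternal_notch_y, 0.15 * h),
            umbilicus_y=default(self.umbilicus_y, 0.93 * h),
            breast_center_y=default(self.breast_center_y, 0.45 * h),
            breast_offset_x=default(self.breast_offset_x, 0.225 * w),
            semi_axis_a=default(self.semi_axis_a, 0.175 * w),
            semi_axis_b=default(self.semi_axis_b, 0.155 * h),
            nipple_offset=default(self.nipple_offset, (0.0, 0.02 * h)),
            cm_per_px=default(self.cm_per_px, 53.76 / w),
        )
        out.validate()
        return out

    def validate(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("image must be at least 32x32")
        if self.semi_axis_a is not None and self.semi_axis_a <= 0:
            raise ValueError("semi_axis_a must be positive")
        if self.semi_axis_b is not None and self.semi_axis_b <= 0:
            raise ValueError("semi_axis_b must be positive")
        if self.area_ratio <= 0:
            raise ValueError("area_ratio must be positive")
        if self.exponent < 2.0:
            raise ValueError("superellipse exponent must be >= 2 (convexity)")
        if self.ptosis_drop < 0:
            raise ValueError("ptosis_drop must be non-negative")
        if None not in (self.breast_offset_x, self.semi_axis_a):
            if self.breast_offset_x - self.semi_axis_a * math.sqrt(max(self.area_ratio, 1.0)) <= 0:
                raise ValueError("footprint crosses the midline")


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s], [s, c]])


def _superellipse_xy(theta: np.ndarray, a: float, b_sup: float, b_inf: float, n: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / n)
    b_half = np.where(s > 0, b_inf, b_sup)  # y grows downward: s > 0 is inferior
    y = b_half * np.sign(s) * np.abs(s) ** (2.0 / n)
    return np.column_stack([x, y])


def _footprint_layout(p: TorsoParams, side: Side, theta: np.ndarray) -> np.ndarray:
    scale = math.sqrt(p.area_ratio) if side is Side.LEFT else 1.0
    a = p.semi_axis_a * scale
    b = p.semi_axis_b * scale
    local = _superellipse_xy(theta, a, b, b + p.ptosis_drop, p.exponent)
    rot = _rot(p.rotation_deg_left if side is Side.LEFT else p.rotation_deg_right)
    sign = 1.0 if side is Side.LEFT else -1.0  # patient-left is viewer +x
    center = np.array([p.midline_x + sign * p.breast_offset_x, p.breast_center_y])
    return local @ rot.T + center


def _station_angles(side: Side) -> np.ndarray:
    k = np.arange(FOOTPRINT_POINTS_PER_SIDE)
    step = 2.0 * math.pi / FOOTPRINT_POINTS_PER_SIDE
    if side is Side.LEFT:  # medial-superior start, clockwise as displayed
        return math.radians(225.0) + k * step
    return math.radians(315.0) - k * step


def _layout_landmarks(p: TorsoParams) -> dict:
    """All 30 landmark coordinates in the untilted layout frame."""
    out = {
        LandmarkRole.STERNAL_NOTCH: np.array([p.midline_x, p.sternal_notch_y]),
        LandmarkRole.UMBILICUS: np.array([p.midline_x, p.umbilicus_y]),
    }
    for side in Side:
        fp = _footprint_layout(p, side, _station_angles(side))
        for role, xy in zip(FOOTPRINT_ROLES[side], fp):
            out[role] = xy
        sign = 1.0 if side is Side.LEFT else -1.0
        center = np.array([p.midline_x + sign * p.breast_offset_x, p.breast_center_y])
        nip = center + np.asarray(p.nipple_offset, dtype=float)
        if side is Side.LEFT:
            nip = nip + np.asarray(p.nipple_displacement, dtype=float)
        out[NIPPLE[side]] = nip
    return out


# ---------------------------------------------------------------------------
# Closed-form reference values (deliberately free of the geometry module:
# shoelace, convex clipping and frame arithmetic are written out here so the
# generator is an independent oracle for the analysis code).
# ---------------------------------------------------------------------------

def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _perimeter(v: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def _clip_convex(subject: np.ndarray, clipper: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex subject by a convex clipper."""
    def inside(pts, a, b, sign):
        return sign * ((b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])) >= 0

    sign = 1.0 if _shoelace(clipper) > 0 else -1.0
    output = subject
    m = len(clipper)
    for i in range(m):
        if len(output) == 0:
            break
        a, b = clipper[i], clipper[(i + 1) % m]
        keep = inside(output, a, b, sign)
        new = []
        n = len(output)
        for j in range(n):
            cur, nxt = output[j], output[(j + 1) % n]
            if keep[j]:
                new.append(cur)
            if keep[j] != keep[(j + 1) % n]:
                d = nxt - cur
                denom = (b[0] - a[0]) * d[1] - (b[1] - a[1]) * d[0]
                t = ((b[0] - a[0]) * (a[1] - cur[1]) - (b[1] - a[1]) * (a[0] - cur[0])) / denom
                new.append(cur + t * d)
        output = np.array(new) if new else np.empty((0, 2))
    return output


def _lower_arc(fp: np.ndarray) -> float:
    """Inferior-border polyline length: ordinal stations 7..13 of the ring."""
    pts = fp[6:13]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _arc_over_mound(chord: float, depth: float, segments: int = 512) -> float:
    """Length of z(s) = depth*sin(pi*s/chord) over s in [0, chord]."""
    if chord <= 0:
        return 0.0
    s = np.linspace(0.0, chord, segments + 1)
    z = depth * np.sin(math.pi * s / chord)
    return float(np.sum(np.hypot(np.diff(s), np.diff(z))))


@dataclass(frozen=True)
class AnalyticTruth:
    """Closed-form reference values for one torso."""

    measurements: MeasurementSet
    report: AsymmetryReport
    true_lower_pole_cm: SidePair
    anchor: CalibrationAnchor
    calibration: Calibration


def _analytic_truth(p: TorsoParams, marks: dict) -> AnalyticTruth:
    mid_x = p.midline_x
    k = p.cm_per_px
    sn = marks[LandmarkRole.STERNAL_NOTCH]

    per_side = {}
    for side in Side:
        nip = marks[NIPPLE[side]]
        fp = np.array([marks[r] for r in FOOTPRINT_ROLES[side]])
        sn_n = float(np.linalg.norm(nip - sn))
        n_s = abs(float(nip[0] - mid_x))
        ymax = fp[:, 1].max()
        lows = fp[fp[:, 1] >= ymax - 1e-12]
        low = lows[np.argmin(lows[:, 0])]
        chord = float(np.linalg.norm(nip - low))
        bbw = float(fp[:, 0].max() - fp[:, 0].min())
        scale = math.sqrt(p.area_ratio) if side is Side.LEFT else 1.0
        depth = 0.35 * p.semi_axis_b * scale + 0.9 * p.ptosis_drop
        per_side[side] = {
            "sn_n": sn_n, "n_s": n_s, "chord": chord, "bbw": bbw,
            "fp": fp, "nip": nip, "true_arc": _arc_over_mound(chord, depth),
        }

    L, R = per_side[Side.LEFT], per_side[Side.RIGHT]
    measurements = MeasurementSet(
        sn_to_nipple=SidePair(L["sn_n"] * k, R["sn_n"] * k),
        nipple_to_sternum=SidePair(L["n_s"] * k, R["n_s"] * k),
        nipple_to_imf=SidePair(L["chord"] * k, R["chord"] * k),
        breast_base_width=SidePair(L["bbw"] * k, R["bbw"] * k),
    )

    uL, vL = L["nip"][0] - mid_x, L["nip"][1] - sn[1]
    uR, vR = R["nip"][0] - mid_x, R["nip"][1] - sn[1]
    bra = math.hypot(abs(uL) - abs(uR), vL - vR)
    unr = abs(vL - vR)
    lbc = abs(_lower_arc(L["fp"]) - _lower_arc(R["fp"]))
    bce = abs((L["fp"][:, 1].max() - L["nip"][1]) - (R["fp"][:, 1].max() - R["nip"][1]))
    bcd = abs(_perimeter(L["fp"]) - _perimeter(R["fp"]))
    area_l, area_r = abs(_shoelace(L["fp"])), abs(_shoelace(R["fp"]))
    bad = abs(area_l - area_r)
    fpR_mirror = R["fp"].copy()
    fpR_mirror[:, 0] = 2.0 * mid_x - fpR_mirror[:, 0]
    clipped = _clip_convex(L["fp"], fpR_mirror)
    inter = abs(_shoelace(clipped)) if len(clipped) >= 3 else 0.0
    bod = max(0.0, area_l + area_r - 2.0 * inter)

    ref_len = 0.5 * (L["sn_n"] + R["sn_n"])
    ref_area = max(area_l, area_r)

    def length(px):
        return IndexValue(px, px / ref_len, px * k)

    def area(px2):
        return IndexValue(px2, px2 / ref_area, px2 * k * k)

    report = AsymmetryReport(
        bra=length(bra), lbc=length(lbc), unr=length(unr), bce=length(bce),
        bcd=length(bcd), bad=area(bad), bod=area(bod),
        reference_length_px=ref_len, reference_area_px2=ref_area,
    )
    anchor = CalibrationAnchor(AnchorKind.SN_TO_NIPPLE_R, R["sn_n"] * k)
    return AnalyticTruth(
        measurements=measurements,
        report=report,
        true_lower_pole_cm=SidePair(L["true_arc"] * k, R["true_arc"] * k),
        anchor=anchor,
        calibration=Calibration(k, anchor),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render(p: TorsoParams, rng: np.random.Generator) -> np.ndarray:
    w, h = p.width, p.height
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # evaluate shapes in the untilted layout frame
    r = _rot(-p.tilt_deg)
    lx = r[0, 0] * (xx - cx) + r[0, 1] * (yy - cy) + cx
    ly = r[1, 0] * (xx - cx) + r[1, 1] * (yy - cy) + cy

    img = np.full((h, w), 30.0)
    body_rho = np.hypot((lx - p.midline_x) / (0.36 * w),
                        (ly - 0.55 * h) / (0.46 * h))
    img += 90.0 * np.clip((1.0 - body_rho) * 8.0, 0.0, 1.0)

    marks = _layout_landmarks(p)
    n = p.exponent
    for side in Side:
        scale = math.sqrt(p.area_ratio) if side is Side.LEFT else 1.0
        a = p.semi_axis_a * scale
        b_sup = p.semi_axis_b * scale
        b_inf = b_sup + p.ptosis_drop
        sign = 1.0 if side is Side.LEFT else -1.0
        center = np.array([p.midline_x + sign * p.breast_offset_x, p.breast_center_y])
        rot = _rot(-(p.rotation_deg_left if side is Side.LEFT else p.rotation_deg_right))
        bx = rot[0, 0] * (lx - center[0]) + rot[0, 1] * (ly - center[1])
        by = rot[1, 0] * (lx - center[0]) + rot[1, 1] * (ly - center[1])
        b_half = np.where(by > 0, b_inf, b_sup)
        rho = (np.abs(bx / a) ** n + np.abs(by / b_half) ** n) ** (1.0 / n)
        img += 85.0 * np.clip(1.0 - rho, 0.0, 1.0) ** 0.6

    r_nip = max(2.5, 0.016 * min(w, h))
    for side in Side:
        nip = marks[NIPPLE[side]]
        dist = np.hypot(lx - nip[0], ly - nip[1])
        img = np.where(dist <= r_nip, 235.0, img)

    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class TorsoSample:
    image: ImageRecord
    truth: LandmarkSet
    analytic: AnalyticTruth
    params: TorsoParams


def generate(params: TorsoParams) -> TorsoSample:
    """Render one torso and package it with its ground truth."""
    p = params.resolved()
    rng = np.random.default_rng(p.seed)
    marks = _layout_landmarks(p)

    # global tilt about the image center
    cx, cy = (p.width - 1) / 2.0, (p.height - 1) / 2.0
    rot = _rot(p.tilt_deg)
    center = np.array([cx, cy])
    tilted = {role: rot @ (xy - center) + center for role, xy in marks.items()}

    points = [LandmarkPoint(role, float(xy[0]), float(xy[1])) for role, xy in tilted.items()]
    truth = LandmarkSet(points, p.width, p.height, metadata={"seed": p.seed})
    image = ImageRecord(_render(p, rng), 8)
    return TorsoSample(image=image, truth=truth, analytic=_analytic_truth(p, marks), params=p)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDistribution:
    """Sampling ranges for torso parameters (px values at 256-px scale).

    Defaults emulate a post-surgical validation cohort.  Patients
    evaluated with photometric asymmetry tools have had tissue resected
    from one side, so the asymmetries are large: nipple malposition on
    the order of 0-4 cm (the displacement sigma of 10 px corresponds to
    about 2 cm at the default 0.21 cm/px scale), footprint area ratios
    spanning roughly 0.65-1.5, a spread of ptosis, and a small camera
    roll.
    """

    nipple_displacement_sigma: float = 10.0
    area_ratio_log_sigma: float = 0.18
    area_ratio_clip: tuple = (0.65, 1.5)
    ptosis_range: tuple = (0.0, 12.0)
    tilt_sigma_deg: float = 2.0
    axis_jitter: tuple = (0.9, 1.1)
    center_jitter_sigma: float = 3.0
    landmark_jitter_sigma: float = 2.0
    noise_sigma: float = 4.0

    def sample_params(self, rng: np.random.Generator, width: int = 256,
                      height: int = 256, seed: int = 0) -> TorsoParams:
        f = width / _REF_SIZE
        base = TorsoParams(width=width, height=height).resolved()
        area_ratio = float(np.clip(math.exp(rng.normal(0.0, self.area_ratio_log_sigma)),
                                   *self.area_ratio_clip))
        semi_a = base.semi_axis_a * rng.uniform(*self.axis_jitter)
        semi_b = base.semi_axis_b * rng.uniform(*self.axis_jitter)
        disp = rng.normal(0.0, self.nipple_displacement_sigma * f, size=2)
        lim = 0.3 * semi_b
        norm = float(np.linalg.norm(disp))
        if norm > lim:
            disp = disp * (lim / norm)
        offset_x = base.breast_offset_x + rng.normal(0, self.center_jitter_sigma * f)
        # keep the scaled footprint clear of the midline
        offset_x = max(offset_x, semi_a * math.sqrt(max(area_ratio, 1.0)) + 2.0 * f)
        return TorsoParams(
            width=width, height=height,
            tilt_deg=float(rng.normal(0.0, self.tilt_sigma_deg)),
            sternal_notch_y=base.sternal_notch_y + rng.normal(0, self.landmark_jitter_sigma * f),
            umbilicus_y=base.umbilicus_y + rng.normal(0, self.landmark_jitter_sigma * f),
            breast_center_y=base.breast_center_y + rng.normal(0, self.center_jitter_sigma * f),
            breast_offset_x=offset_x,
            semi_axis_a=semi_a, semi_axis_b=semi_b,
            nipple_displacement=(float(disp[0]), float(disp[1])),
            area_ratio=area_ratio,
            ptosis_drop=float(rng.uniform(self.ptosis_range[0] * f, self.ptosis_range[1] * f)),
            noise_sigma=self.noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def generate_cohort(n: int, dist: CohortDistribution | None = None, seed: int = 0,
                    width: int = 256, height: int = 256):
    """Draw n torsos i.i.d. from the parameter distribution.

    Returns (samples, manifest); the manifest records every sampled
    parameter, one row per subject.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    dist = dist or CohortDistribution()
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    for i in range(n):
        p = dist.sample_params(rng, width=width, height=height)
        sample = generate(p)
        samples.append(sample)
        row = {"subject": f"torso_{i:04d}"}
        rp = sample.params
        for name in ("width", "height", "midline_x", "tilt_deg", "sternal_notch_y",
                     "umbilicus_y", "breast_center_y", "breast_offset_x", "semi_axis_a",
                     "semi_axis_b", "exponent", "area_ratio", "ptosis_drop",
                     "noise_sigma", "cm_per_px", "seed"):
            row[name] = getattr(rp, name)
        row["nipple_displacement_x"], row["nipple_displacement_y"] = rp.nipple_displacement
        rows.append(row)
    return samples, pd.DataFrame(rows)
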