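import numpy as np
import pytest

from mammometry.model import (
    FOOTPRINT_ROLES,
    LandmarkPoint,
    LandmarkRole,
    LandmarkSet,
    Side,
)
from mammometry.synthetic import TorsoParams, generate


def circle_footprint(center, radius, side, n=13):
    """13 points on a circle in the schema's ordinal ordering."""
    start = np.radians(225.0 if side is Side.LEFT else 315.0)
    sign = 1.0 if side is Side.LEFT else -1.0
    theta = start + sign * np.arange(n) * 2 * np.pi / n
    return np.column_stack([center[0] + radius * np.cos(theta),
                            center[1] + radius * np.sin(theta)])


def build_set(sn=(200.0, 60.0), um=(200.0, 360.0),
              nip_l=(290.0, 180.0), nip_r=(110.0, 180.0),
              fp_l_center=(290.0, 175.0), fp_r_center=(110.0, 175.0),
              radius=60.0, image_size=(400, 420)):
    """Hand-built valid landmark set with circular footprints."""
    pts = [
        LandmarkPoint(LandmarkRole.STERNAL_NOTCH, *sn),
        LandmarkPoint(LandmarkRole.UMBILICUS, *um),
        LandmarkPoint(LandmarkRole.NIPPLE_L, *nip_l),
        LandmarkPoint(LandmarkRole.NIPPLE_R, *nip_r),
    ]
    for side, center in ((Side.LEFT, fp_l_center), (Side.RIGHT, fp_r_center)):
        for role, (x, y) in zip(FOOTPRINT_ROLES[side], circle_footprint(center, radius, side)):
            pts.append(LandmarkPoint(role, float(x), float(y)))
    return LandmarkSet(pts, image_size[0], image_size[1])


@pytest.fixture
def symmetric_set():
    return build_set()


@pytest.fixture
def symmetric_torso():
    return generate(TorsoParams(seed=0))


@pytest.fixture
def asymmetric_torso():
    return generate(TorsoParams(
        tilt_deg=5.0, nipple_displacement=(4.0, -6.0),
        area_ratio=1.15, ptosis_drop=10.0, seed=3))


def random_valid_set(rng):
    """Random valid landmark set (jittered star-convex footprints)."""
    sn = rng.uniform(150, 250, 2) * [1, 0.4]
    um = sn + [rng.uniform(-30, 30), rng.uniform(200, 300)]
    sets = []
    for side, cx in ((Side.LEFT, 290.0), (Side.RIGHT, 110.0)):
        center = np.array([cx + rng.uniform(-10, 10), 175 + rng.uniform(-10, 10)])
        radii = rng.uniform(45, 70, 13)
        # smooth radii so the 13-gon stays simple and star-shaped
        radii = np.convolve(np.r_[radii[-2:], radii, radii[:2]], np.ones(5) / 5, "valid")
        start = np.radians(225.0 if side is Side.LEFT else 315.0)
        sign = 1.0 if side is Side.LEFT else -1.0
        theta = start + sign * np.arange(13) * 2 * np.pi / 13
        fp = np.column_stack([center[0] + radii * np.cos(theta),
                              center[1] + radii * np.sin(theta)])
        sets.append((center, fp))
    pts = [
        LandmarkPoint(LandmarkRole.STERNAL_NOTCH, float(sn[0]), float(sn[1])),
        LandmarkPoint(LandmarkRole.UMBILICUS, float(um[0]), float(um[1])),
        LandmarkPoint(LandmarkRole.NIPPLE_L, *map(float, sets[0][0] + rng.uniform(-8, 8, 2))),
        LandmarkPoint(LandmarkRole.NIPPLE_R, *map(float, sets[1][0] + rng.uniform(-8, 8, 2))),
    ]
    for (center, fp), side in zip(sets, (Side.LEFT, Side.RIGHT)):
        for role, (x, y) in zip(FOOTPRINT_ROLES[side], fp):
            pts.append(LandmarkPoint(role, float(x), float(y)))
    return LandmarkSet(pts, 400, 480)


def rotate_set(lset, angle_deg, center=(200.0, 200.0)):
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.asarray(center)
    coords = (lset.as_array() - c) @ rot.T + c
    out = lset.replace_coordinates(coords)
    out.image_width = out.image_height = None
    return out


def translate_set(lset, dx, dy):
    out = lset.replace_coordinates(lset.as_array() + [dx, dy])
    out.image_width = out.image_height = None
    return out


def scale_set(lset, k, center=(0.0, 0.0)):
    c = np.asarray(center, dtype=float)
    out = lset.replace_coordinates((lset.as_array() - c) * k + c)
    out.image_width = out.image_height = None
    return out
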