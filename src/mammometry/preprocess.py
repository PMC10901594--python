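"""Image standardization with exact landmark propagation.

Three steps, matching a conventional photogrammetric intake pipeline:

1. ``correct_ratio`` — letterbox the frame to a target aspect ratio by
   symmetric constant-value padding.  Padding (never anisotropic
   scaling) is used because stretching would corrupt the pixel distance
   ratios that centimeter calibration depends on.
2. ``standardize_size`` — isotropic resize so the long side hits a
   target, which scales every pixel distance by exactly one factor s.
3. ``normalize_8bit`` — per-image linear min-max mapping to [0, 255].

Every geometric step returns an :class:`AffineTransform2D` so landmark
coordinates move analytically with the pixels rather than being
re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from PIL import Image

from .model import AffineTransform2D, ImageRecord, LandmarkSet

DEFAULT_ASPECT = Fraction(3, 4)  # width:height
DEFAULT_LONG_SIDE = 1024


@dataclass(frozen=True)
class PreprocessResult:
    image: ImageRecord
    transform: AffineTransform2D
    target_size: tuple  # (width, height)


def parse_aspect(text) -> float:
    """Parse "3:4" / "0.75" style aspect (width over height)."""
    if isinstance(text, (int, float, Fraction)):
        value = float(text)
    else:
        parts = str(text).split(":")
        value = float(parts[0]) / float(parts[1]) if len(parts) == 2 else float(parts[0])
    if value <= 0:
        raise ValueError(f"aspect ratio must be positive, got {text!r}")
    return value


def correct_ratio(image: ImageRecord, target_aspect=DEFAULT_ASPECT, pad_value: int = 0) -> PreprocessResult:
    """Letterbox to the target width:height ratio with symmetric padding.

    The pad total is split as evenly as whole pixels allow (top/left
    gets the smaller half) and the transform records the integer
    translation, so no source pixel is resampled.
    """
    aspect = parse_aspect(target_aspect)
    w, h = image.width, image.height
    if w / h < aspect:  # too narrow: pad width
        out_w, out_h = int(round(h * aspect)), h
    else:  # too wide (or exact): pad height
        out_w, out_h = w, int(round(w / aspect))
    pad_x, pad_y = out_w - w, out_h - h
    left, top = pad_x // 2, pad_y // 2
    shape = (out_h, out_w) + image.pixels.shape[2:]
    canvas = np.full(shape, pad_value, dtype=image.pixels.dtype)
    canvas[top:top + h, left:left + w] = image.pixels
    return PreprocessResult(
        ImageRecord(canvas, image.bit_depth),
        AffineTransform2D.translation(left, top),
        (out_w, out_h),
    )


def standardize_size(image: ImageRecord, long_side: int = DEFAULT_LONG_SIDE) -> PreprocessResult:
    """Isotropic bilinear resize so max(width, height) == long_side.

    The transform is the pixel-center-consistent scaling
    x_out = (x_in + 1/2) s - 1/2, whose linear part is pure scaling by
    s = long_side / max(w, h); pixel distances therefore scale by
    exactly s.
    """
    if long_side < 32:
        raise ValueError(f"long_side must be >= 32, got {long_side}")
    w, h = image.width, image.height
    if max(w, h) < 1:
        raise ValueError("degenerate image")
    s = long_side / max(w, h)
    out_w = long_side if w >= h else max(1, int(round(w * s)))
    out_h = long_side if h > w else max(1, int(round(h * s)))
    if (out_w, out_h) == (w, h):
        return PreprocessResult(image, AffineTransform2D.identity(), (w, h))
    mode = "I;16" if image.bit_depth == 16 else None
    im = Image.fromarray(image.pixels, mode=mode)
    resized = np.asarray(im.resize((out_w, out_h), Image.Resampling.BILINEAR))
    t = AffineTransform2D.scaling(s, 0.5 * s - 0.5, 0.5 * s - 0.5)
    return PreprocessResult(ImageRecord(resized.astype(image.pixels.dtype), image.bit_depth), t, (out_w, out_h))


def normalize_8bit(image: ImageRecord) -> ImageRecord:
    """Per-image linear min-max mapping to [0, 255], rounded half-up.

    A constant image maps to all zeros (the one deterministic choice
    that avoids 0/0).  Idempotent on its own output.
    """
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = 255.0 * (px - lo) / (hi - lo)
    out = np.floor(out + 0.5).astype(np.uint8)
    return ImageRecord(out, 8)


def apply_transform(landmarks: LandmarkSet, t: AffineTransform2D,
                    out_size: tuple | None = None) -> LandmarkSet:
    """Map every landmark through an invertible affine transform."""
    moved = landmarks.replace_coordinates(t.apply(landmarks.as_array()))
    if out_size is not None:
        moved.image_width, moved.image_height = int(out_size[0]), int(out_size[1])
    return moved


def standard_pipeline(image: ImageRecord, aspect=DEFAULT_ASPECT,
                      long_side: int = DEFAULT_LONG_SIDE) -> PreprocessResult:
    """correct_ratio -> standardize_size -> normalize_8bit, transforms composed."""
    r1 = correct_ratio(image, aspect)
    r2 = standardize_size(r1.image, long_side)
    final = normalize_8bit(r2.image)
    t = r2.transform.compose(r1.transform)
    return PreprocessResult(final, t, r2.target_size)
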