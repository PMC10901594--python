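"""Annotation (JSON) and image (PNG/JPEG/TIFF) input/output.

Annotation dialect::

    {"schema": "sbest-landmarks-v1",
     "image": {"width": W, "height": H},
     "points": [{"role": "NIPPLE_L", "x": ..., "y": ...}, ...],
     "metadata": {...}}

Writing is canonical: fixed key order, points in canonical role order,
floats serialized with shortest round-trip representation — two writes
of the same set are byte-identical and the read/write round trip is
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .model import (
    ImageRecord,
    LandmarkPoint,
    LandmarkRole,
    LandmarkSet,
    SchemaError,
    validate_landmark_set,
)

SCHEMA_NAME = "sbest-landmarks-v1"

_KNOWN_KEYS = {"schema", "image", "points", "metadata"}


class AnnotationParseError(ValueError):
    """The file is not valid JSON or not the expected dialect."""


class ValidationError(ValueError):
    """A landmark set violates schema invariants."""


def read_annotation(path) -> LandmarkSet:
    """Read a landmark annotation file, validating the 30-role schema.

    Unknown top-level keys are preserved in ``metadata``.
    """
    try:
        raw = Path(path).read_text(encoding="utf-8")
        doc = json.loads(raw)
    except (OSError, UnicodeDecodeError) as exc:
        raise AnnotationParseError(f"cannot read annotation {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or "points" not in doc:
        raise AnnotationParseError(f"{path}: not a landmark annotation document")

    points = []
    for entry in doc["points"]:
        name = entry.get("role")
        try:
            role = LandmarkRole[name]
        except KeyError:
            raise SchemaError(f"unknown role: {name}") from None
        points.append(LandmarkPoint(role, float(entry["x"]), float(entry["y"])))

    image = doc.get("image") or {}
    metadata = dict(doc.get("metadata") or {})
    for key in doc:
        if key not in _KNOWN_KEYS:
            metadata[key] = doc[key]
    lset = LandmarkSet(points, image.get("width"), image.get("height"), metadata)
    violations = validate_landmark_set(lset)
    if violations:
        raise ValidationError(f"{path}: " + "; ".join(violations))
    return lset


def write_annotation(lset: LandmarkSet, path) -> None:
    """Write the canonical annotation JSON (validates before any write)."""
    violations = validate_landmark_set(lset)
    if violations:
        raise ValidationError("; ".join(violations))
    doc = {
        "schema": SCHEMA_NAME,
        "image": {"width": lset.image_width, "height": lset.image_height},
        "points": [
            {"role": p.role.name, "x": p.x, "y": p.y} for p in lset.points.values()
        ],
        "metadata": {k: lset.metadata[k] for k in sorted(lset.metadata)},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


_SUPPORTED = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


class FormatError(ValueError):
    pass


def read_image(path) -> ImageRecord:
    p = Path(path)
    if p.suffix.lower() not in _SUPPORTED:
        raise FormatError(f"unsupported image format: {p.suffix}")
    with Image.open(p) as im:
        if im.mode in ("I;16", "I;16B", "I;16L", "I"):
            arr = np.asarray(im, dtype=np.uint16)
            return ImageRecord(arr, 16)
        if im.mode == "L":
            return ImageRecord(np.asarray(im, dtype=np.uint8), 8)
        rgb = im.convert("RGB")
        return ImageRecord(np.asarray(rgb, dtype=np.uint8), 8)


def write_image(rec: ImageRecord, path) -> None:
    p = Path(path)
    if p.suffix.lower() not in _SUPPORTED:
        raise FormatError(f"unsupported image format: {p.suffix}")
    arr = rec.pixels
    if rec.bit_depth == 16:
        if arr.ndim != 2:
            raise FormatError("16-bit output supported for grayscale only")
        im = Image.fromarray(arr.astype(np.uint16))
    else:
        im = Image.fromarray(arr.astype(np.uint8))
    im.save(p)
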