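"""End-to-end analysis orchestration and batch processing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import (
    AnchorKind,
    Calibration,
    CalibrationAnchor,
    MeasurementSet,
    SidePair,
    calibrate,
    clinical_measurements,
)
from .indices import AsymmetryReport, IndexValue, compute_indices, render_overlap
from .io import read_annotation
from .model import LandmarkSet

REPORT_SCHEMA_VERSION = 1

_ANCHOR_ALIASES = {
    "sn-r": AnchorKind.SN_TO_NIPPLE_R,
    "sn-l": AnchorKind.SN_TO_NIPPLE_L,
    "n-n": AnchorKind.NIPPLE_TO_NIPPLE,
}


def parse_anchor(text: str) -> CalibrationAnchor:
    """Parse an ``sn-r:20.8`` style anchor specification (cm)."""
    try:
        kind_txt, value_txt = text.split(":")
        kind = _ANCHOR_ALIASES.get(kind_txt.strip().lower()) or AnchorKind[kind_txt.strip().upper()]
        return CalibrationAnchor(kind, float(value_txt))
    except (ValueError, KeyError) as exc:
        raise ValueError(
            f"bad anchor {text!r}; expected kind:cm with kind one of "
            "sn-r, sn-l, n-n (sternal notch to right/left nipple, nipple to nipple)"
        ) from exc


class MissingAnchorError(ValueError):
    pass


@dataclass
class AnalysisReport:
    """Machine-readable analysis output for one subject."""

    subject: str
    measurements: MeasurementSet | None
    indices: AsymmetryReport
    calibration: Calibration | None
    provenance: dict

    def to_dict(self) -> dict:
        def pair(p: SidePair):
            return {"L": p.left, "R": p.right}

        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "subject": self.subject,
            "provenance": self.provenance,
            "calibration": None,
            "measurements_cm": None,
            "indices": {},
        }
        if self.calibration is not None:
            doc["calibration"] = {
                "cm_per_px": self.calibration.cm_per_px,
                "anchor_kind": self.calibration.anchor_used.kind.value,
                "anchor_cm": self.calibration.anchor_used.length_cm,
            }
        if self.measurements is not None:
            m = self.measurements
            doc["measurements_cm"] = {
                "sn_to_nipple": pair(m.sn_to_nipple),
                "nipple_to_sternum": pair(m.nipple_to_sternum),
                "nipple_to_imf": pair(m.nipple_to_imf),
                "breast_base_width": pair(m.breast_base_width),
            }
        for name in ("bra", "lbc", "unr", "bce", "bcd", "bad", "bod"):
            iv: IndexValue = self.indices[name]
            doc["indices"][name] = {
                "px": iv.px, "dimensionless": iv.dimensionless, "physical": iv.physical,
            }
        doc["indices"]["reference_length_px"] = self.indices.reference_length_px
        doc["indices"]["reference_area_px2"] = self.indices.reference_area_px2
        return doc

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_analysis(landmarks, anchors=(), subject: str = "subject",
                 dimensionless: bool = False, config: dict | None = None,
                 render_path=None) -> AnalysisReport:
    """Landmarks -> calibration -> measurements -> indices -> report.

    ``landmarks`` is a LandmarkSet or an annotation path.  Without any
    anchor the analysis must be explicitly requested as dimensionless;
    otherwise the error names the three accepted anchor kinds.
    """
    provenance = {"software": f"mammometry {__version__}",
                  "config": dict(config or {})}
    if not isinstance(landmarks, LandmarkSet):
        provenance["landmarks_sha256"] = _file_digest(landmarks)
        provenance["landmarks_file"] = str(landmarks)
        landmarks = read_annotation(landmarks)

    anchors = list(anchors)
    cal = None
    measurements = None
    if anchors:
        cal = calibrate(landmarks, anchors)
        measurements = clinical_measurements(landmarks, cal)
    elif not dimensionless:
        raise MissingAnchorError(
            "no calibration anchor supplied; pass one of sn-r (sternal notch to "
            "right nipple), sn-l (sternal notch to left nipple) or n-n (nipple "
            "to nipple) in cm, or request --dimensionless explicitly")

    indices = compute_indices(landmarks, cal)
    if render_path is not None:
        render_overlap(landmarks, render_path)
    return AnalysisReport(subject=subject, measurements=measurements,
                          indices=indices, calibration=cal, provenance=provenance)


def report_rows(report: AnalysisReport) -> list:
    """Flat rows (subject, measure, side, value) for aggregate CSVs."""
    rows = []
    if report.measurements is not None:
        for _, r in report.measurements.to_frame().iterrows():
            rows.append({"subject": report.subject, "measure": r["measure"],
                         "side": r["side"], "value": r["value_cm"], "units": "cm"})
    for _, r in report.indices.to_frame().iterrows():
        rows.append({"subject": report.subject, "measure": r["index"],
                     "side": "", "value": r["dimensionless_value"],
                     "units": "dimensionless"})
    return rows


def batch(directory, anchors=(), dimensionless: bool = False,
          config: dict | None = None):
    """Analyze every ``*.json`` annotation in a directory.

    Returns (DataFrame, failures).  Per-file failures are collected and
    the run continues; rows are ordered by file name for stability.
    """
    directory = Path(directory)
    rows, failures = [], []
    for path in sorted(directory.glob("*.json")):
        if path.name.endswith(".png.json") or path.name == "manifest.json":
            continue
        try:
            rep = run_analysis(path, anchors=anchors, subject=path.stem,
                               dimensionless=dimensionless, config=config)
            rows.extend(report_rows(rep))
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            failures.append((path.name, str(exc)))
    columns = ["subject", "measure", "side", "value", "units"]
    return pd.DataFrame(rows, columns=columns), failures
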