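"""Read and write planar count images and ROI sets.

Two image dialects are supported:

* ``text`` — tab-delimited matrix, one row per line, dot decimal separator,
  no header.  Locale independent and trivially diffable.
* ``dicom`` — single-frame Explicit VR Little Endian file with 16-bit
  unsigned pixels; the acquisition phase is stored in the series-description
  field.

ROI sets are stored as a small tagged-JSON schema shared with :mod:`.roi`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _dicom
from .errors import FormatError, SchemaError, ValidationError
from .roi import OvalROI, PolygonROI, RectROI, ROISet

__all__ = ["PlanarImage", "read_planar", "write_planar", "read_roiset", "write_roiset"]

PHASES = ("early", "late")


@dataclass(frozen=True)
class PlanarImage:
    """2D nonnegative count matrix with acquisition metadata.

    ``counts`` is float64 internally so that noise-free expectation images
    (non-integral) are representable; both file dialects are lossless for
    integral counts.
    """

    counts: np.ndarray
    phase: str = "early"
    subject_id: str = ""
    pixel_spacing_mm: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError(f"counts must be a non-empty 2D matrix, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValidationError("counts contain non-finite values")
        if arr.min() < 0:
            raise ValidationError(f"negative count {arr.min()} not allowed")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")
        object.__setattr__(self, "counts", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape

    def scaled(self, factor: float) -> "PlanarImage":
        return PlanarImage(self.counts * factor, self.phase, self.subject_id, self.pixel_spacing_mm)


# ---------------------------------------------------------------------------
# Planar images
# ---------------------------------------------------------------------------

def write_planar(image: PlanarImage, path: str, format: str = "text") -> None:
    """Write *image* to *path*; lossless for integer counts in both dialects."""
    if format == "text":
        arr = image.counts
        if np.allclose(arr, np.rint(arr), atol=1e-9):
            np.savetxt(path, np.rint(arr).astype(np.int64), fmt="%d", delimiter="\t")
        else:
            np.savetxt(path, arr, fmt="%.12g", delimiter="\t")
    elif format == "dicom":
        blob = _dicom.encode(
            image.counts,
            series_description=image.phase,
            patient_id=image.subject_id,
            pixel_spacing=image.pixel_spacing_mm,
        )
        with open(path, "wb") as fh:
            fh.write(blob)
    else:
        raise ValueError(f"unknown image format {format!r}")


def read_planar(
    path: str,
    format: str = "text",
    phase: Optional[str] = None,
    subject_id: str = "",
) -> PlanarImage:
    """Read a planar image.

    For the text dialect the phase comes from the *phase* argument (or a
    ``<path>.json`` sidecar written alongside); for DICOM it is taken from
    the series-description field unless overridden.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "text":
        try:
            arr = np.loadtxt(path, delimiter="\t", ndmin=2, dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: not a tab-delimited numeric matrix ({exc})") from exc
        if arr.size == 0:
            raise FormatError(f"{path}: empty matrix")
        if np.min(arr) < 0:
            raise FormatError(f"{path}: negative count entries are invalid")
        if phase is None:
            sidecar = path + ".json"
            if os.path.exists(sidecar):
                with open(sidecar) as fh:
                    meta = json.load(fh)
                phase = meta.get("phase", "early")
                subject_id = subject_id or meta.get("subject_id", "")
            else:
                phase = "early"
        if np.allclose(arr, np.rint(arr), atol=1e-9):
            arr = np.rint(arr)
        return PlanarImage(arr, phase=phase, subject_id=subject_id)
    if format == "dicom":
        with open(path, "rb") as fh:
            counts, attrs = _dicom.decode(fh.read())
        return PlanarImage(
            counts,
            phase=phase or attrs.get("series_description") or "early",
            subject_id=subject_id or attrs.get("patient_id", ""),
            pixel_spacing_mm=_parse_spacing(attrs.get("pixel_spacing")),
        )
    raise ValueError(f"unknown image format {format!r}")


def _parse_spacing(text: Optional[str]) -> Optional[Tuple[float, float]]:
    if not text:
        return None
    parts = text.split("\\")
    if len(parts) != 2:
        return None
    return (float(parts[0]), float(parts[1]))


# ---------------------------------------------------------------------------
# ROI sets (tagged JSON)
# ---------------------------------------------------------------------------

def _roi_to_dict(roi) -> dict:
    if isinstance(roi, RectROI):
        return {"type": "rect", "x0": roi.x0, "y0": roi.y0, "w": roi.w, "h": roi.h}
    if isinstance(roi, OvalROI):
        return {"type": "oval", "cx": roi.cx, "cy": roi.cy, "rx": roi.rx, "ry": roi.ry}
    if isinstance(roi, PolygonROI):
        return {"type": "polygon", "vertices": [list(v) for v in roi.vertices]}
    raise SchemaError(f"cannot serialize ROI of type {type(roi).__name__}")


def _roi_from_dict(d: dict):
    try:
        kind = d["type"]
    except (KeyError, TypeError) as exc:
        raise SchemaError("ROI object lacks a 'type' tag") from exc
    try:
        if kind == "rect":
            return RectROI(d["x0"], d["y0"], d["w"], d["h"])
        if kind == "oval":
            return OvalROI(d["cx"], d["cy"], d["rx"], d["ry"])
        if kind == "polygon":
            return PolygonROI(d["vertices"])
    except ValidationError as exc:
        raise SchemaError(f"invalid {kind} ROI: {exc}") from exc
    except KeyError as exc:
        raise SchemaError(f"{kind} ROI missing field {exc}") from exc
    raise SchemaError(f"unknown ROI type tag {kind!r}")


def write_roiset(roiset: ROISet, path: str) -> None:
    doc = {
        "schema": "hmquant-roiset-1",
        "method": roiset.method,
        "rater": roiset.rater,
        "cardiac": _roi_to_dict(roiset.cardiac),
        "mediastinal": _roi_to_dict(roiset.mediastinal),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_roiset(path: str) -> ROISet:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("cardiac", "mediastinal", "method"):
        if key not in doc:
            raise SchemaError(f"{path}: missing key {key!r}")
    return ROISet(
        cardiac=_roi_from_dict(doc["cardiac"]),
        mediastinal=_roi_from_dict(doc["mediastinal"]),
        method=doc["method"],
        rater=doc.get("rater", ""),
    )
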