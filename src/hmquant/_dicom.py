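"""Minimal single-frame DICOM codec (Explicit VR Little Endian only).

Supports exactly the subset this package writes: a Part 10 file with the
standard 128-byte preamble, a small file-meta group and a secondary-capture
style dataset holding one unsigned 16-bit monochrome frame.  Reading walks
the element stream and tolerates unknown tags; anything outside the Explicit
VR Little Endian transfer syntax or with more than one frame is rejected.
"""

from __future__ import annotations

import struct
from typing import Dict, Tuple

import numpy as np

from .errors import FormatError, RangeError, UnsupportedInputError

_TRANSFER_SYNTAX = "1.2.840.10008.1.2.1"  # Explicit VR Little Endian
_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"  # Secondary Capture Image Storage
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.2025.1"

TAG_SERIES_DESCRIPTION = (0x0008, 0x103E)
TAG_PATIENT_ID = (0x0010, 0x0020)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_NUMBER_OF_FRAMES = (0x0028, 0x0008)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)

_SHORT_VRS = {
    "AE", "AS", "AT", "CS", "DA", "DS", "DT", "FL", "FD", "IS", "LO", "LT",
    "PN", "SH", "SL", "SS", "ST", "TM", "UI", "UL", "US",
}
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}


def _element(group: int, elem: int, vr: str, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in ("UI",) else b"\x00"
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    if len(value) > 0xFFFF:
        raise RangeError(f"value too long for short VR {vr}")
    return head + struct.pack("<H", len(value)) + value


def _str_el(group: int, elem: int, vr: str, text: str) -> bytes:
    return _element(group, elem, vr, text.encode("ascii"))


def _us_el(group: int, elem: int, value: int) -> bytes:
    return _element(group, elem, "US", struct.pack("<H", value))


def encode(
    counts: np.ndarray,
    series_description: str = "",
    patient_id: str = "",
    pixel_spacing: Tuple[float, float] | None = None,
    sop_instance_uid: str = _IMPLEMENTATION_UID + ".1",
) -> bytes:
    """Encode a 2D nonnegative integer array as a single-frame DICOM file."""
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2D matrix, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-9):
            raise RangeError("DICOM dialect stores integers; counts are not integral")
        arr = rounded.astype(np.int64)
    if arr.min() < 0:
        raise RangeError("negative counts cannot be written")
    if arr.max() > 0xFFFF:
        raise RangeError(
            f"max count {int(arr.max())} exceeds the 16-bit unsigned range of "
            "the DICOM dialect"
        )
    pixels = arr.astype("<u2").tobytes()

    meta = b"".join(
        [
            _str_el(0x0002, 0x0002, "UI", _SOP_CLASS),
            _str_el(0x0002, 0x0003, "UI", sop_instance_uid),
            _str_el(0x0002, 0x0010, "UI", _TRANSFER_SYNTAX),
            _str_el(0x0002, 0x0012, "UI", _IMPLEMENTATION_UID),
        ]
    )
    meta = _element(0x0002, 0x0000, "UL", struct.pack("<I", len(meta))) + meta

    dataset = [
        _str_el(0x0008, 0x0016, "UI", _SOP_CLASS),
        _str_el(0x0008, 0x0018, "UI", sop_instance_uid),
        _str_el(0x0008, 0x0060, "CS", "NM"),
        _str_el(*TAG_SERIES_DESCRIPTION, "LO", series_description),
        _str_el(*TAG_PATIENT_ID, "LO", patient_id),
        _us_el(0x0028, 0x0002, 1),  # SamplesPerPixel
        _str_el(0x0028, 0x0004, "CS", "MONOCHROME2"),
        _us_el(*TAG_ROWS, arr.shape[0]),
        _us_el(*TAG_COLUMNS, arr.shape[1]),
        _us_el(0x0028, 0x0100, 16),  # BitsAllocated
        _us_el(0x0028, 0x0101, 16),  # BitsStored
        _us_el(0x0028, 0x0102, 15),  # HighBit
        _us_el(0x0028, 0x0103, 0),   # PixelRepresentation (unsigned)
    ]
    if pixel_spacing is not None:
        ps = f"{pixel_spacing[0]:g}\\{pixel_spacing[1]:g}"
        dataset.append(_str_el(*TAG_PIXEL_SPACING, "DS", ps))
    dataset.append(_element(*TAG_PIXEL_DATA, "OW", pixels))

    return b"\x00" * 128 + b"DICM" + meta + b"".join(dataset)


def decode(data: bytes) -> Tuple[np.ndarray, Dict[str, str]]:
    """Decode a file produced by :func:`encode` (or a compatible subset).

    Returns ``(counts, attrs)`` where *attrs* holds ``series_description``,
    ``patient_id`` and optionally ``pixel_spacing``.
    """
    if len(data) < 132 or data[128:132] != b"DICM":
        raise FormatError("not a DICOM Part 10 file (missing DICM magic)")
    pos = 132
    elements: Dict[Tuple[int, int], bytes] = {}
    n = len(data)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4 : pos + 6].decode("ascii", errors="replace")
        if vr in _LONG_VRS:
            if pos + 12 > n:
                raise FormatError("truncated DICOM element header")
            (length,) = struct.unpack_from("<I", data, pos + 8)
            body_at = pos + 12
        elif vr in _SHORT_VRS:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            body_at = pos + 8
        else:
            raise FormatError(
                f"unsupported or implicit VR {vr!r} at offset {pos}; only "
                "Explicit VR Little Endian is supported"
            )
        if length == 0xFFFFFFFF:
            raise UnsupportedInputError("undefined-length (encapsulated) elements unsupported")
        if body_at + length > n:
            raise FormatError("truncated DICOM element body")
        elements[(group, elem)] = data[body_at : body_at + length]
        pos = body_at + length

    ts = elements.get((0x0002, 0x0010), b"").decode("ascii").rstrip("\x00 ")
    if ts and ts != _TRANSFER_SYNTAX:
        raise UnsupportedInputError(f"unsupported transfer syntax {ts}")

    if TAG_NUMBER_OF_FRAMES in elements:
        raw_frames = elements[TAG_NUMBER_OF_FRAMES].decode("ascii").strip("\x00 ")
        nframes = int(raw_frames or "1")
        if nframes != 1:
            raise UnsupportedInputError(f"multi-frame DICOM ({nframes} frames) unsupported")

    for tag, name in ((TAG_ROWS, "Rows"), (TAG_COLUMNS, "Columns"), (TAG_PIXEL_DATA, "PixelData")):
        if tag not in elements:
            raise FormatError(f"missing required element {name}")
    (rows,) = struct.unpack("<H", elements[TAG_ROWS])
    (cols,) = struct.unpack("<H", elements[TAG_COLUMNS])
    bits = struct.unpack("<H", elements.get((0x0028, 0x0100), b"\x10\x00"))[0]
    if bits != 16:
        raise UnsupportedInputError(f"only 16-bit pixel data supported, got {bits}")
    raw = elements[TAG_PIXEL_DATA]
    if len(raw) < rows * cols * 2:
        raise FormatError("pixel data shorter than Rows x Columns x 2 bytes")
    counts = np.frombuffer(raw[: rows * cols * 2], dtype="<u2").reshape(rows, cols)

    attrs: Dict[str, str] = {
        "series_description": elements.get(TAG_SERIES_DESCRIPTION, b"")
        .decode("ascii")
        .strip("\x00 "),
        "patient_id": elements.get(TAG_PATIENT_ID, b"").decode("ascii").strip("\x00 "),
    }
    if TAG_PIXEL_SPACING in elements:
        attrs["pixel_spacing"] = elements[TAG_PIXEL_SPACING].decode("ascii").strip("\x00 ")
    return counts.astype(np.int64), attrs
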