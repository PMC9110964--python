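"""Minimal DICOM parser for uncompressed explicit-VR little-endian CT slices.

Only the small tag subset needed to assemble a scalar CT volume is decoded;
everything else is skipped.  Sequences with undefined length and transfer
syntaxes other than explicit VR little endian are rejected.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import FormatError

# VRs whose value length is encoded on 4 bytes after 2 reserved bytes
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

TAG_SERIES_UID = (0x0020, 0x000E)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def parse_dicom_file(path: str | Path) -> dict:
    """Parse one DICOM file into a ``{(group, element): (vr, raw bytes)}`` dict."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise FormatError(f"{path.name}: missing DICM magic — not a DICOM part-10 file")
    elements: dict = {}
    pos = 132
    n = len(data)
    while pos + 8 <= n:
        group, element = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4 : pos + 6]
        if not vr.isalpha() or not vr.isupper():
            raise FormatError(
                f"{path.name}: implicit-VR or corrupt element at offset {pos}; "
                "only explicit VR little endian is supported"
            )
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            pos += 8
        if length == 0xFFFFFFFF:
            raise FormatError(
                f"{path.name}: undefined-length element "
                f"({group:04X},{element:04X}) is not supported"
            )
        if pos + length > n:
            raise FormatError(f"{path.name}: truncated element ({group:04X},{element:04X})")
        elements[(group, element)] = (vr.decode(), data[pos : pos + length])
        pos += length
    return elements


def _get(elements: dict, tag: tuple, path: Path):
    if tag not in elements:
        raise FormatError(f"{path.name}: required tag ({tag[0]:04X},{tag[1]:04X}) missing")
    return elements[tag]


def decode_string(elements: dict, tag: tuple, path: Path) -> str:
    _, raw = _get(elements, tag, path)
    return raw.decode("ascii", errors="replace").strip().strip("\x00")


def decode_floats(elements: dict, tag: tuple, path: Path) -> np.ndarray:
    _, raw = _get(elements, tag, path)
    text = raw.decode("ascii", errors="replace").strip().strip("\x00")
    return np.array([float(x) for x in text.split("\\")])


def decode_us(elements: dict, tag: tuple, path: Path) -> int:
    _, raw = _get(elements, tag, path)
    return struct.unpack("<H", raw[:2])[0]


def read_slice(path: str | Path) -> dict:
    """Decode one CT slice into geometry, rescale and a stored-value pixel array."""
    path = Path(path)
    el = parse_dicom_file(path)
    rows = decode_us(el, TAG_ROWS, path)
    cols = decode_us(el, TAG_COLUMNS, path)
    bits = decode_us(el, TAG_BITS_ALLOCATED, path)
    signed = bool(decode_us(el, TAG_PIXEL_REPRESENTATION, path)) \
        if TAG_PIXEL_REPRESENTATION in el else False
    if bits not in (8, 16):
        raise FormatError(f"{path.name}: unsupported BitsAllocated={bits}")
    dtype = {(8, False): np.uint8, (8, True): np.int8,
             (16, False): np.uint16, (16, True): np.int16}[(bits, signed)]
    _, raw_pixels = _get(el, TAG_PIXEL_DATA, path)
    expected = rows * cols * bits // 8
    if len(raw_pixels) < expected:
        raise FormatError(f"{path.name}: pixel data shorter than Rows*Columns")
    pixels = np.frombuffer(raw_pixels[:expected], dtype=dtype).reshape(rows, cols)

    slope = 1.0
    intercept = 0.0
    if TAG_RESCALE_SLOPE in el:
        slope = float(decode_floats(el, TAG_RESCALE_SLOPE, path)[0])
    if TAG_RESCALE_INTERCEPT in el:
        intercept = float(decode_floats(el, TAG_RESCALE_INTERCEPT, path)[0])

    return {
        "path": path,
        "series_uid": decode_string(el, TAG_SERIES_UID, path)
        if TAG_SERIES_UID in el else "",
        "position_xyz": decode_floats(el, TAG_IMAGE_POSITION, path),
        "orientation_xyz": decode_floats(el, TAG_IMAGE_ORIENTATION, path),
        "pixel_spacing_rowcol": decode_floats(el, TAG_PIXEL_SPACING, path),
        "slope": slope,
        "intercept": intercept,
        "pixels": pixels,
    }
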