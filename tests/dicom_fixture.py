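"""Writes tiny explicit-VR little-endian CT DICOM series for reader tests."""

import struct
from pathlib import Path

import numpy as np

_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}


def _element(group: int, elem: int, vr: str, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in ("UI", "OB") else b" "
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr.encode(), 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr.encode(), len(value)) + value


def _ds(*values) -> bytes:
    return "\\".join(f"{v:.10g}" for v in values).encode()


def write_ct_slice(
    path: Path,
    pixels: np.ndarray,
    position_xyz,
    orientation_xyz=(1, 0, 0, 0, 1, 0),
    pixel_spacing_rowcol=(1.0, 1.0),
    series_uid: str = "1.2.3.4",
    sop_uid: str = "1.2.3.4.1",
    slope: float = 1.0,
    intercept: float = 0.0,
    instance_number: int = 1,
) -> None:
    pixels = np.ascontiguousarray(pixels, dtype="<i2")
    rows, cols = pixels.shape
    body = b"".join([
        _element(0x0008, 0x0016, "UI", b"1.2.840.10008.5.1.4.1.1.2"),
        _element(0x0008, 0x0018, "UI", sop_uid.encode()),
        _element(0x0008, 0x0060, "CS", b"CT"),
        _element(0x0020, 0x000D, "UI", b"1.2.3"),
        _element(0x0020, 0x000E, "UI", series_uid.encode()),
        _element(0x0020, 0x0013, "IS", str(instance_number).encode()),
        _element(0x0020, 0x0032, "DS", _ds(*position_xyz)),
        _element(0x0020, 0x0037, "DS", _ds(*orientation_xyz)),
        _element(0x0028, 0x0002, "US", struct.pack("<H", 1)),
        _element(0x0028, 0x0010, "US", struct.pack("<H", rows)),
        _element(0x0028, 0x0011, "US", struct.pack("<H", cols)),
        _element(0x0028, 0x0030, "DS", _ds(*pixel_spacing_rowcol)),
        _element(0x0028, 0x0100, "US", struct.pack("<H", 16)),
        _element(0x0028, 0x0101, "US", struct.pack("<H", 16)),
        _element(0x0028, 0x0102, "US", struct.pack("<H", 15)),
        _element(0x0028, 0x0103, "US", struct.pack("<H", 1)),
        _element(0x0028, 0x1052, "DS", _ds(intercept)),
        _element(0x0028, 0x1053, "DS", _ds(slope)),
        _element(0x7FE0, 0x0010, "OW", pixels.tobytes()),
    ])
    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + body)


def write_ct_series(
    directory: Path,
    stored: np.ndarray,
    spacing=(0.625, 0.7, 0.7),
    origin_xyz=(0.0, 0.0, 0.0),
    slope: float = 1.0,
    intercept: float = 0.0,
    shuffle: bool = True,
) -> None:
    """Write a (z, y, x) int16 stored-value volume as one slice file per z.

    File order on disk is shuffled by default so readers must sort by
    position rather than by filename or instance number.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nz = stored.shape[0]
    order = list(range(nz))
    if shuffle:
        order = order[::-1]
    for file_idx, z in enumerate(order):
        write_ct_slice(
            directory / f"slice_{file_idx:03d}.dcm",
            stored[z],
            position_xyz=(origin_xyz[0], origin_xyz[1], origin_xyz[2] + z * spacing[0]),
            pixel_spacing_rowcol=(spacing[1], spacing[2]),
            sop_uid=f"1.2.3.4.{z + 1}",
            slope=slope,
            intercept=intercept,
            instance_number=z + 1,
        )
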