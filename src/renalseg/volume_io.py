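"""Reading CT volumes (DICOM series, MetaImage) and writing masks and reports.

Axis bookkeeping: file formats order axes x-fastest (x, y, z) while the
package indexes arrays (z, y, x); vectors are reversed and direction
matrices conjugated by the axis-reversal permutation at the I/O boundary.
A numpy array in C order already stores x fastest, so voxel buffers move
between numpy and MetaImage untouched.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dicom
from .core import (
    BinaryMask,
    CTVolume,
    FormatError,
    Geometry,
    GeometryError,
)
from .config import SegmentationConfig
from .volumetrics import VolumeMetrics

__all__ = [
    "read_dicom_series",
    "read_metaimage",
    "write_metaimage",
    "write_mask",
    "read_mask",
    "MetricsReport",
    "write_metrics",
    "read_metrics",
]

_J = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # zyx <-> xyz reversal

_MET_TO_DTYPE = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory_path: str | Path, phase: str = "native") -> CTVolume:
    """Read a single-series CT DICOM directory into a Hounsfield-unit volume.

    Slices are ordered by Image Position Patient projected on the slice
    normal (instance numbers are ignored).  Rescale slope/intercept are
    applied, so the returned voxels are in HU.

    Raises
    ------
    FormatError
        on non-DICOM files, mixed series, or missing mandatory tags —
        naming the offending slice.
    GeometryError
        on inconsistent orientation or non-uniform slice spacing (>1%).
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"{directory_path}: no files found")
    slices = [_dicom.read_slice(p) for p in files]

    ref = slices[0]
    for s in slices[1:]:
        if s["series_uid"] != ref["series_uid"]:
            raise FormatError(
                f"{s['path'].name}: belongs to a different series "
                f"({s['series_uid']!r} != {ref['series_uid']!r})"
            )
        if s["pixels"].shape != ref["pixels"].shape:
            raise FormatError(f"{s['path'].name}: slice dimensions differ from the series")
        if not np.allclose(s["orientation_xyz"], ref["orientation_xyz"], atol=1e-4):
            raise GeometryError(f"{s['path'].name}: image orientation differs from the series")
        if not np.allclose(s["pixel_spacing_rowcol"], ref["pixel_spacing_rowcol"], atol=1e-6):
            raise GeometryError(f"{s['path'].name}: pixel spacing differs from the series")

    row_dir_xyz = ref["orientation_xyz"][:3]   # direction of increasing column index
    col_dir_xyz = ref["orientation_xyz"][3:]   # direction of increasing row index
    normal_xyz = np.cross(row_dir_xyz, col_dir_xyz)

    positions = np.array([float(np.dot(s["position_xyz"], normal_xyz)) for s in slices])
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = positions[order]

    if len(slices) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise GeometryError(f"{directory_path}: duplicate slice positions in series")
        mean_step = float(steps.mean())
        if np.max(np.abs(steps - mean_step)) > 0.01 * mean_step:
            raise GeometryError(
                f"{directory_path}: non-uniform slice spacing "
                f"(steps range {steps.min():.6g}..{steps.max():.6g} mm)"
            )
        slice_spacing = mean_step
    else:
        slice_spacing = 1.0

    voxels = np.stack(
        [s["pixels"].astype(np.float64) * s["slope"] + s["intercept"] for s in slices]
    )

    row_sp, col_sp = ref["pixel_spacing_rowcol"]
    spacing_zyx = np.array([slice_spacing, row_sp, col_sp])
    origin_zyx = slices[0]["position_xyz"][::-1]
    # columns of the direction matrix: physical direction of each index axis (z, y, x)
    dir_xyz_by_index_zyx = np.column_stack([normal_xyz, col_dir_xyz, row_dir_xyz])
    direction_zyx = _J @ dir_xyz_by_index_zyx

    geometry = Geometry(spacing=spacing_zyx, origin=origin_zyx, direction=direction_zyx)
    return CTVolume(voxels=voxels, geometry=geometry, phase=phase,
                    intensity_domain="hounsfield")


# ---------------------------------------------------------------------------
# MetaImage
# ---------------------------------------------------------------------------

def _parse_mhd_header(path: Path):
    """Parse MetaImage header key/values; returns (header dict, data offset or None)."""
    header: dict[str, str] = {}
    data_offset = None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            try:
                text = line.decode("ascii")
            except UnicodeDecodeError as exc:
                raise FormatError(f"{path.name}: non-ASCII header line") from exc
            if "=" not in text:
                raise FormatError(f"{path.name}: malformed header line {text!r}")
            key, _, value = text.partition("=")
            key = key.strip()
            header[key] = value.strip()
            if key == "ElementDataFile":
                if header[key] == "LOCAL":
                    data_offset = fh.tell()
                break
    if "ElementDataFile" not in header:
        raise FormatError(f"{path.name}: header lacks ElementDataFile")
    return header, data_offset


def _read_metaimage_raw(file_path: Path):
    header, data_offset = _parse_mhd_header(file_path)

    ndims = int(header.get("NDims", "0"))
    if ndims != 3:
        raise FormatError(f"{file_path.name}: only 3D images are supported (NDims={ndims})")
    channels = int(header.get("ElementNumberOfChannels", "1"))
    if channels != 1:
        raise FormatError(f"{file_path.name}: vector-valued images are not supported")
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise FormatError(f"{file_path.name}: big-endian data is not supported")

    elem_type = header.get("ElementType", "")
    if elem_type not in _MET_TO_DTYPE:
        raise FormatError(f"{file_path.name}: unsupported ElementType {elem_type!r}")
    dtype = np.dtype(_MET_TO_DTYPE[elem_type])

    dims_xyz = [int(x) for x in header["DimSize"].split()]
    spacing_xyz = np.array([float(x) for x in header.get("ElementSpacing", "1 1 1").split()])
    offset_xyz = np.array([float(x) for x in header.get("Offset", "0 0 0").split()])
    if "TransformMatrix" in header:
        mat_xyz = np.array([float(x) for x in header["TransformMatrix"].split()]).reshape(3, 3)
    else:
        mat_xyz = np.eye(3)

    nbytes = int(np.prod(dims_xyz)) * dtype.itemsize
    if data_offset is not None:
        with open(file_path, "rb") as fh:
            fh.seek(data_offset)
            raw = fh.read()
    else:
        raw_path = file_path.parent / header["ElementDataFile"]
        if not raw_path.exists():
            raise FormatError(f"{file_path.name}: data file {raw_path.name} not found")
        raw = raw_path.read_bytes()

    if header.get("CompressedData", "False").lower() == "true":
        raw = zlib.decompress(raw)
    if len(raw) < nbytes:
        raise FormatError(f"{file_path.name}: data shorter than DimSize implies")

    voxels = np.frombuffer(raw[:nbytes], dtype=dtype).reshape(dims_xyz[::-1])  # (z, y, x)
    geometry = Geometry(
        spacing=spacing_xyz[::-1],
        origin=offset_xyz[::-1],
        direction=_J @ mat_xyz @ _J,
    )
    return voxels, geometry


def read_metaimage(file_path: str | Path, phase: str = "native") -> CTVolume:
    """Read a scalar MetaImage (.mha local-data or .mhd + raw) volume in HU."""
    voxels, geometry = _read_metaimage_raw(Path(file_path))
    return CTVolume(voxels=np.asarray(voxels, dtype=np.float64), geometry=geometry,
                    phase=phase, intensity_domain="hounsfield")


def write_metaimage(voxels: np.ndarray, geometry: Geometry, file_path: str | Path) -> None:
    """Write a (z, y, x) voxel array as an uncompressed MetaImage."""
    file_path = Path(file_path)
    voxels = np.ascontiguousarray(voxels)
    if voxels.dtype == bool:
        voxels = voxels.astype(np.uint8)
    if voxels.dtype not in _DTYPE_TO_MET:
        voxels = voxels.astype(np.float64)
    elem_type = _DTYPE_TO_MET[voxels.dtype]

    mat_xyz = _J @ geometry.direction @ _J
    header_lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = " + " ".join(f"{v:.10g}" for v in mat_xyz.ravel()),
        "Offset = " + " ".join(f"{v:.10g}" for v in geometry.origin[::-1]),
        "ElementSpacing = " + " ".join(f"{v:.10g}" for v in geometry.spacing[::-1]),
        "DimSize = " + " ".join(str(d) for d in voxels.shape[::-1]),
        f"ElementType = {elem_type}",
    ]
    if file_path.suffix == ".mhd":
        raw_path = file_path.with_suffix(".raw")
        header_lines.append(f"ElementDataFile = {raw_path.name}")
        file_path.write_text("\n".join(header_lines) + "\n")
        raw_path.write_bytes(voxels.tobytes())
    else:
        header_lines.append("ElementDataFile = LOCAL")
        with open(file_path, "wb") as fh:
            fh.write(("\n".join(header_lines) + "\n").encode("ascii"))
            fh.write(voxels.tobytes())


def write_volume(volume: CTVolume, file_path: str | Path) -> None:
    """Persist a CTVolume's voxels and geometry as MetaImage (intensities as float64)."""
    write_metaimage(volume.voxels, volume.geometry, file_path)


def write_mask(mask: BinaryMask, file_path: str | Path) -> None:
    """Persist a mask as an 8-bit (0/1) MetaImage with the mask's geometry."""
    write_metaimage(mask.bits.astype(np.uint8), mask.geometry, file_path)


def read_mask(file_path: str | Path, label: str = "") -> BinaryMask:
    voxels, geometry = _read_metaimage_raw(Path(file_path))
    return BinaryMask(bits=voxels != 0, geometry=geometry, label=label)


# ---------------------------------------------------------------------------
# Metrics report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Carrier for the volumetric outputs plus enough context to reproduce them."""

    metrics: VolumeMetrics
    config_used: SegmentationConfig
    voxel_counts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.config_used is None:
            raise ValueError("MetricsReport requires a config snapshot")
        if not isinstance(self.metrics, VolumeMetrics):
            raise ValueError("metrics must be a VolumeMetrics instance")

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(),
            "config_used": dataclasses.asdict(self.config_used),
            "voxel_counts": {k: int(v) for k, v in self.voxel_counts.items()},
            "provenance": dict(self.provenance),
        }


def write_metrics(report: MetricsReport, file_path: str | Path) -> None:
    Path(file_path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_metrics(file_path: str | Path) -> MetricsReport:
    data = json.loads(Path(file_path).read_text())
    if "config_used" not in data or data["config_used"] is None:
        raise ValueError(f"{file_path}: metrics report lacks a config snapshot")
    return MetricsReport(
        metrics=VolumeMetrics.from_dict(data["metrics"]),
        config_used=SegmentationConfig(**data["config_used"]),
        voxel_counts=data.get("voxel_counts", {}),
        provenance=data.get("provenance", {}),
    )
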