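"""Core grid types shared by every stage of the pipeline.

Conventions used throughout the package
---------------------------------------
* Voxel arrays are indexed ``(slice, row, column)`` — i.e. ``(z, y, x)``.
* ``spacing``, ``origin`` and physical points are expressed in the same
  ``(z, y, x)`` axis order, in millimetres.
* Indices are 0-based.  The physical position of the *centre* of voxel
  ``i`` is ``origin + direction @ (i * spacing)``.
* ``direction`` is an orthonormal 3x3 matrix (determinant +-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "RenalSegError",
    "FormatError",
    "GeometryError",
    "DomainError",
    "AlignmentError",
    "RegistrationError",
    "MeshError",
    "PhantomSpecError",
    "Geometry",
    "CTVolume",
    "BinaryMask",
]


class RenalSegError(Exception):
    """Base class for all package errors."""


class FormatError(RenalSegError):
    """A file or stream does not conform to the expected format."""


class GeometryError(RenalSegError):
    """Inconsistent or invalid physical geometry."""


class DomainError(RenalSegError):
    """Operation applied to a volume in the wrong intensity domain."""


class AlignmentError(RenalSegError):
    """Mask/volume pair does not share a common grid."""


class RegistrationError(RenalSegError):
    """Co-registration could not be performed."""


class MeshError(RenalSegError):
    """Surface extraction or mesh validation failure."""


class PhantomSpecError(RenalSegError):
    """Phantom specification violates an intensity-band invariant."""


IntensityDomain = Literal["hounsfield", "shifted"]
Phase = Literal["native", "delayed"]


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    return a


def _as_mat3(m) -> np.ndarray:
    a = np.asarray(m, dtype=float).reshape(3, 3)
    return a


@dataclass(frozen=True)
class Geometry:
    """Physical placement of a 3D grid: spacing/origin/direction in (z, y, x) order."""

    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "spacing", _as_vec3(self.spacing))
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        object.__setattr__(self, "direction", _as_mat3(self.direction))
        if not np.all(self.spacing > 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        d = self.direction
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix is not orthonormal")

    @classmethod
    def default(cls, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> "Geometry":
        return cls(spacing=spacing, origin=origin, direction=np.eye(3))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        """Physical position (mm, zyx order) of voxel-centre ``index`` (may be fractional)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (self.direction @ (idx * self.spacing).T).T

    def physical_to_index(self, point) -> np.ndarray:
        """Continuous index coordinates of physical point(s) ``point``."""
        p = np.asarray(point, dtype=float)
        return (self.direction.T @ (p - self.origin).T).T / self.spacing

    def same_grid_as(self, other: "Geometry", atol: float = 1e-6) -> bool:
        return (
            np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class CTVolume:
    """A scalar CT volume with physical geometry and a phase tag.

    ``voxels`` hold Hounsfield units when ``intensity_domain == "hounsfield"``
    and continuous values in [0, 255] when ``intensity_domain == "shifted"``.
    """

    voxels: np.ndarray
    geometry: Geometry
    phase: Phase = "native"
    intensity_domain: IntensityDomain = "hounsfield"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3D voxel grid, got ndim={self.voxels.ndim}")
        if self.phase not in ("native", "delayed"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.intensity_domain not in ("hounsfield", "shifted"):
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")
        if self.intensity_domain == "shifted":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-9 or hi > 255 + 1e-9:
                raise DomainError(
                    f"shifted-domain voxels must lie in [0, 255]; found [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        return self.geometry.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.geometry.origin

    @property
    def direction(self) -> np.ndarray:
        return self.geometry.direction

    def with_voxels(self, voxels: np.ndarray, **kwargs) -> "CTVolume":
        """New volume sharing this volume's geometry with replaced voxels/attributes."""
        return CTVolume(
            voxels=voxels,
            geometry=self.geometry,
            phase=kwargs.get("phase", self.phase),
            intensity_domain=kwargs.get("intensity_domain", self.intensity_domain),
        )


@dataclass
class BinaryMask:
    """A boolean grid sharing a source volume's geometry."""

    bits: np.ndarray
    geometry: Geometry
    label: str = ""

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3:
            raise GeometryError(f"expected a 3D mask, got ndim={self.bits.ndim}")

    @property
    def shape(self) -> tuple:
        return self.bits.shape

    @property
    def voxel_count(self) -> int:
        return int(self.bits.sum())

    def with_bits(self, bits: np.ndarray, label: str | None = None) -> "BinaryMask":
        return BinaryMask(bits=bits, geometry=self.geometry,
                          label=self.label if label is None else label)


def check_same_grid(a, b, what: str = "operands") -> None:
    """Raise :class:`AlignmentError` unless the two grids are identical."""
    if a.shape != b.shape:
        raise AlignmentError(f"{what} have different shapes: {a.shape} vs {b.shape}")
    ga = a.geometry if hasattr(a, "geometry") else a
    gb = b.geometry if hasattr(b, "geometry") else b
    if not ga.same_grid_as(gb):
        raise AlignmentError(f"{what} have different geometries")
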