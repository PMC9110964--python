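"""Stone volume (SV), pelvicalyceal-system volume (PSV) and their ratio."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import BinaryMask, check_same_grid

__all__ = ["VolumeMetrics", "mask_volume_mm3", "compute_metrics"]

PSVConvention = Literal["union", "exclusive"]


@dataclass(frozen=True)
class VolumeMetrics:
    """SV and PSV in mm^3; ratio is SV/PSV and NaN when PSV == 0.

    ``psv_convention`` records whether stone voxels inside the segmented
    collecting system counted toward PSV (``union``, default) or were
    removed first (``exclusive``).
    """

    sv_mm3: float
    psv_mm3: float
    ratio: float
    psv_convention: PSVConvention = "union"

    def __post_init__(self):
        if self.sv_mm3 < 0 or self.psv_mm3 < 0:
            raise ValueError("volumes must be non-negative")
        if self.psv_mm3 > 0:
            expected = self.sv_mm3 / self.psv_mm3
            if not math.isclose(self.ratio, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"ratio {self.ratio} inconsistent with SV/PSV = {expected}"
                )

    @property
    def ratio_defined(self) -> bool:
        return self.psv_mm3 > 0

    def to_dict(self) -> dict:
        return {
            "sv_mm3": self.sv_mm3,
            "psv_mm3": self.psv_mm3,
            "sv_cm3": self.sv_mm3 / 1000.0,
            "psv_cm3": self.psv_mm3 / 1000.0,
            "ratio": None if not self.ratio_defined else self.ratio,
            "psv_convention": self.psv_convention,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "VolumeMetrics":
        ratio = data.get("ratio")
        return cls(
            sv_mm3=float(data["sv_mm3"]),
            psv_mm3=float(data["psv_mm3"]),
            ratio=float("nan") if ratio is None else float(ratio),
            psv_convention=data.get("psv_convention", "union"),
        )


def mask_volume_mm3(mask: BinaryMask) -> float:
    """True-voxel count times the voxel volume (product of spacings)."""
    return mask.voxel_count * mask.geometry.voxel_volume_mm3


def compute_metrics(result, psv_convention: PSVConvention = "union") -> VolumeMetrics:
    """Volumetrics from a :class:`~renalseg.segmentation.SegmentationResult`.

    ``union``: the collecting-system mask as segmented (stone voxels inside
    it count toward PSV).  ``exclusive``: collecting-system minus calculus.
    An empty collecting-system mask yields PSV = 0 and an undefined (NaN)
    ratio rather than an exception.
    """
    if psv_convention not in ("union", "exclusive"):
        raise ValueError(f"unknown PSV convention {psv_convention!r}")
    calculus: BinaryMask = result.calculus
    collecting: BinaryMask = result.collecting_system
    check_same_grid(calculus, collecting, "calculus and collecting-system masks")

    sv = mask_volume_mm3(calculus)
    if psv_convention == "exclusive":
        psv_bits = collecting.bits & ~calculus.bits
        psv = int(psv_bits.sum()) * collecting.geometry.voxel_volume_mm3
    else:
        psv = mask_volume_mm3(collecting)

    if psv > 0:
        ratio = sv / psv
    else:
        ratio = float("nan")
    return VolumeMetrics(sv_mm3=sv, psv_mm3=psv, ratio=ratio,
                         psv_convention=psv_convention)
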