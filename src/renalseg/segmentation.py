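"""Histogram thresholding, binary morphology and the three named segmentations.

The skeleton (bone) is the tissue class whose intensity band is constant
across both phases; it is obtained by intersecting the cleaned, dilated
native-band mask with the cleaned delayed-band mask.  The collecting system
is the delayed-only contrast-filled space: the cleaned delayed-band mask
minus the skeleton.  The calculus is the very-high-intensity class of the
native phase.

Structuring elements are solid voxel cubes; morphology runs in index space
(element sizes are in voxels, anisotropic spacing is ignored).  For a cube
of edge d the per-axis offsets are ``arange(d) - d//2``; the grid exterior
is background for erosion and dilation alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PipelineConfig, SegmentationConfig
from .core import BinaryMask, CTVolume, DomainError, check_same_grid
from .preprocess import band_shift, coregister, median_denoise, resample

__all__ = [
    "IntensityHistogram",
    "SegmentationResult",
    "compute_histogram",
    "binarize",
    "erode",
    "dilate",
    "particle_removal",
    "intersect_masks",
    "subtract_masks",
    "segment_skeleton",
    "segment_collecting_system",
    "segment_calculus",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityHistogram:
    """Voxel counts over equal-width bins on the shifted 0-255 scale."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, np.int64))
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need exactly len(counts)+1 bin edges")


def compute_histogram(volume: CTVolume, n_bins: int = 256) -> IntensityHistogram:
    """Histogram of a shifted-domain volume over [0, 255]."""
    if volume.intensity_domain != "shifted":
        raise DomainError("compute_histogram expects a shifted-domain volume")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(volume.voxels, bins=n_bins, range=(0.0, 255.0))
    return IntensityHistogram(bin_edges=edges, counts=counts)


def binarize(volume: CTVolume, lower: float, upper: float, label: str = "") -> BinaryMask:
    """Mask of voxels with lower <= value <= upper (both bounds inclusive)."""
    if volume.intensity_domain != "shifted":
        raise DomainError("binarize expects a shifted-domain volume")
    if lower > upper:
        raise ValueError(f"lower ({lower}) must be <= upper ({upper})")
    bits = (volume.voxels >= lower) & (volume.voxels <= upper)
    return BinaryMask(bits=bits, geometry=volume.geometry, label=label)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def _cube(dim: int) -> np.ndarray:
    if dim < 1:
        raise ValueError("cube dimension must be >= 1")
    return np.ones((dim, dim, dim), dtype=bool)


def _erode_bits(bits: np.ndarray, dim: int) -> np.ndarray:
    return ndimage.binary_erosion(bits, structure=_cube(dim), border_value=0)


def _dilate_bits(bits: np.ndarray, dim: int) -> np.ndarray:
    return ndimage.binary_dilation(bits, structure=_cube(dim), border_value=0)


def erode(mask: BinaryMask, cube_dim: int) -> BinaryMask:
    return mask.with_bits(_erode_bits(mask.bits, cube_dim))


def dilate(mask: BinaryMask, cube_dim: int, iterations: int = 1) -> BinaryMask:
    """Iterated dilation with a solid cube element of edge ``cube_dim``."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    bits = mask.bits
    for _ in range(iterations):
        bits = _dilate_bits(bits, cube_dim)
    return mask.with_bits(bits)


def particle_removal(mask: BinaryMask, cube_dim: int) -> BinaryMask:
    """Opening (erode, dilate) then closing (dilate, erode) with a cube element."""
    bits = mask.bits
    opened = _dilate_bits(_erode_bits(bits, cube_dim), cube_dim)
    closed = _erode_bits(_dilate_bits(opened, cube_dim), cube_dim)
    return mask.with_bits(closed)


# ---------------------------------------------------------------------------
# Mask set algebra
# ---------------------------------------------------------------------------

def intersect_masks(a: BinaryMask, b: BinaryMask, label: str = "") -> BinaryMask:
    check_same_grid(a, b, "masks to intersect")
    return BinaryMask(bits=a.bits & b.bits, geometry=a.geometry, label=label)


def subtract_masks(a: BinaryMask, b: BinaryMask, label: str = "") -> BinaryMask:
    """Voxelwise a AND NOT b."""
    check_same_grid(a, b, "masks to subtract")
    return BinaryMask(bits=a.bits & ~b.bits, geometry=a.geometry, label=label)


# ---------------------------------------------------------------------------
# Named segmentations
# ---------------------------------------------------------------------------

def segment_skeleton(
    native_shifted: CTVolume,
    delayed_shifted_registered: CTVolume,
    config: SegmentationConfig | None = None,
):
    """Six-step bone extraction; returns (skeleton mask, dict of step masks).

    step1: binarize native on the skeleton-native band;
    step2: particle removal of step1 (cube 3);
    step3: dilation of step2;
    step4: binarize delayed on the skeleton-delayed band;
    step5: particle removal of step4 (cube 3);
    step6: intersection of step3 and step5 — the skeleton.
    """
    if config is None:
        config = SegmentationConfig()
    check_same_grid(native_shifted, delayed_shifted_registered, "native and delayed volumes")

    step1 = binarize(native_shifted, config.skeleton_native_lower,
                     config.skeleton_native_upper, label="step1_native_band")
    step2 = particle_removal(step1, config.particle_cube_dim_skeleton)
    step2.label = "step2_particles_removed"
    step3 = dilate(step2, config.dilation_cube_dim, config.dilation_iterations)
    step3.label = "step3_dilated"
    step4 = binarize(delayed_shifted_registered, config.skeleton_delayed_lower,
                     config.skeleton_delayed_upper, label="step4_delayed_band")
    step5 = particle_removal(step4, config.particle_cube_dim_skeleton)
    step5.label = "step5_particles_removed"
    step6 = intersect_masks(step3, step5, label="skeleton")

    intermediates = {
        "step1": step1, "step2": step2, "step3": step3,
        "step4": step4, "step5": step5, "step6": step6,
    }
    return step6, intermediates


def segment_collecting_system(step5: BinaryMask, step6: BinaryMask) -> BinaryMask:
    """Cleaned delayed-band mask minus the skeleton (step5 - step6)."""
    return subtract_masks(step5, step6, label="collecting_system")


def segment_calculus(
    native_shifted: CTVolume, config: SegmentationConfig | None = None
) -> BinaryMask:
    """Stone extraction: binarize the native calculus band, then particle removal."""
    if config is None:
        config = SegmentationConfig()
    band = binarize(native_shifted, config.calculus_lower, config.calculus_upper)
    mask = particle_removal(band, config.particle_cube_dim_calculus)
    mask.label = "calculus"
    return mask


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """All pipeline outputs: the three masks, every intermediate, and context."""

    skeleton: BinaryMask
    collecting_system: BinaryMask
    calculus: BinaryMask
    intermediates: dict = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)
    registration: object = None
    stage_log: list = field(default_factory=list)

    def voxel_counts(self) -> dict:
        counts = {
            "skeleton": self.skeleton.voxel_count,
            "collecting_system": self.collecting_system.voxel_count,
            "calculus": self.calculus.voxel_count,
        }
        counts.update({k: m.voxel_count for k, m in self.intermediates.items()})
        return counts


def _log_stage(log: list, stage: str, **info):
    entry = {"stage": stage, **info}
    log.append(entry)
    logger.info("stage %-22s %s", stage, info)


def run_full_pipeline(
    native: CTVolume,
    delayed: CTVolume,
    config: PipelineConfig | None = None,
    skip_registration: bool = False,
) -> SegmentationResult:
    """Execute the whole flow on Hounsfield-domain inputs.

    band-shift both phases -> median-denoise both -> co-register (native
    fixed, delayed moving) -> resample delayed onto the native grid ->
    skeleton -> collecting system -> calculus.  ``skip_registration``
    assumes the phases are already aligned (identity transform).
    """
    if config is None:
        config = PipelineConfig()
    for vol, name in ((native, "native"), (delayed, "delayed")):
        if vol.intensity_domain != "hounsfield":
            raise DomainError(f"{name} volume must be in the Hounsfield domain")

    log: list = []
    stage = "band_shift"
    try:
        native_s = band_shift(native, config.band_shift)
        delayed_s = band_shift(delayed, config.band_shift)
        _log_stage(log, stage)

        stage = "median_denoise"
        native_d = median_denoise(native_s, config.preprocess.median_radius)
        delayed_d = median_denoise(delayed_s, config.preprocess.median_radius)
        _log_stage(log, stage, radius=config.preprocess.median_radius)

        stage = "coregister"
        if skip_registration:
            from .preprocess import RigidTransform

            registration = None
            delayed_reg = delayed_d
            _log_stage(log, stage, skipped=True)
        else:
            registration = coregister(native_d, delayed_d, config.preprocess)
            delayed_reg = resample(delayed_d, registration.transform, native_d)
            _log_stage(
                log, stage,
                translation_mm=[round(float(t), 4) for t in registration.transform.translation],
                rotation_rad=[round(float(r), 6) for r in registration.transform.rotation],
                converged=registration.converged,
                iterations=registration.iterations_run,
            )

        stage = "segment_skeleton"
        skeleton, intermediates = segment_skeleton(native_d, delayed_reg, config.segmentation)
        _log_stage(log, stage, voxels=skeleton.voxel_count)

        stage = "segment_collecting_system"
        collecting = segment_collecting_system(intermediates["step5"], skeleton)
        _log_stage(log, stage, voxels=collecting.voxel_count)

        stage = "segment_calculus"
        calculus = segment_calculus(native_d, config.segmentation)
        _log_stage(log, stage, voxels=calculus.voxel_count)
    except Exception as exc:
        exc.args = (f"[stage: {stage}] {exc}",)
        raise

    return SegmentationResult(
        skeleton=skeleton,
        collecting_system=collecting,
        calculus=calculus,
        intermediates=intermediates,
        config=config,
        registration=registration,
        stage_log=log,
    )
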