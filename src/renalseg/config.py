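"""Pipeline configuration: intensity bands, structuring elements, optimizer knobs.

All defaults follow the published segmentation flow chart; every value can be
overridden from a YAML (or JSON — YAML is a superset) config file with
top-level sections ``preprocess:`` and ``segmentation:``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "BandShiftSpec",
    "PreprocessSettings",
    "SegmentationConfig",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class BandShiftSpec:
    """Linear intensity transfer mapping an HU band onto the 8-bit display range."""

    input_low: float = -548.0
    input_high: float = 800.0
    output_low: float = 0.0
    output_high: float = 255.0

    def __post_init__(self):
        if not self.input_low < self.input_high:
            raise ValueError("input_low must be < input_high")
        if not self.output_low < self.output_high:
            raise ValueError("output_low must be < output_high")

    def apply(self, value):
        """The transfer function f(v), with clamping outside the input band."""
        import numpy as np

        v = np.asarray(value, dtype=float)
        scale = (self.output_high - self.output_low) / (self.input_high - self.input_low)
        out = self.output_low + (v - self.input_low) * scale
        return np.clip(out, self.output_low, self.output_high)

    def invert(self, value):
        """Inverse map back to HU; exact only for values produced from in-band HU."""
        import numpy as np

        v = np.asarray(value, dtype=float)
        scale = (self.input_high - self.input_low) / (self.output_high - self.output_low)
        return self.input_low + (v - self.output_low) * scale


@dataclass(frozen=True)
class PreprocessSettings:
    """Denoising and co-registration parameters."""

    median_radius: int = 1
    registration_bins: int = 48
    registration_max_iterations: int = 100
    registration_levels: int = 2
    registration_seed: int = 0
    background_hu: float = -548.0

    def __post_init__(self):
        if self.median_radius < 1:
            raise ValueError("median_radius must be >= 1")
        if self.registration_levels < 1:
            raise ValueError("registration_levels must be >= 1")


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds (shifted 0-255 scale) and structuring-element sizes."""

    skeleton_native_lower: float = 117.0
    skeleton_native_upper: float = 180.0
    skeleton_delayed_lower: float = 130.0
    skeleton_delayed_upper: float = 255.0
    calculus_lower: float = 250.0
    calculus_upper: float = 255.0
    particle_cube_dim_skeleton: int = 3
    particle_cube_dim_calculus: int = 2
    dilation_cube_dim: int = 3
    dilation_iterations: int = 1

    def __post_init__(self):
        pairs = [
            ("skeleton_native", self.skeleton_native_lower, self.skeleton_native_upper),
            ("skeleton_delayed", self.skeleton_delayed_lower, self.skeleton_delayed_upper),
            ("calculus", self.calculus_lower, self.calculus_upper),
        ]
        for name, lo, hi in pairs:
            if not lo < hi:
                raise ValueError(f"{name}: lower ({lo}) must be < upper ({hi})")
        for name in ("particle_cube_dim_skeleton", "particle_cube_dim_calculus",
                     "dilation_cube_dim", "dilation_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    band_shift: BandShiftSpec = field(default_factory=BandShiftSpec)
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def to_dict(self) -> dict:
        return {
            "band_shift": dataclasses.asdict(self.band_shift),
            "preprocess": dataclasses.asdict(self.preprocess),
            "segmentation": dataclasses.asdict(self.segmentation),
        }


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`, applying defaults for absent keys."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {"band_shift", "preprocess", "segmentation"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(
        band_shift=BandShiftSpec(**data.get("band_shift", {})),
        preprocess=PreprocessSettings(**data.get("preprocess", {})),
        segmentation=SegmentationConfig(**data.get("segmentation", {})),
    )


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
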