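"""Synthetic dual-phase CT phantom with analytic ground truth.

The phantom places, on a configurable grid: a soft-tissue kidney ellipsoid,
two vertical bone cylinders (rib/spine surrogates), a collecting system
(pelvis ellipsoid plus cylindrical calyx branches) and one or more stone
ellipsoids inside the pelvis.  The delayed phase shares the anatomy but
raises the collecting-system cavity to the contrast intensity and is
resampled through a known rigid misalignment, so the whole pipeline —
registration included — can be validated against closed-form truth.

Tissue means are chosen so that, after the default band shift
f(h) = 255*(h+548)/1348, each class lands in its intended threshold band:
f(40) ~ 111.2 (below 117), f(300) ~ 160.4 (in 117-180 and 130-255),
f(450) ~ 188.8 (in 130-255 only), f(900) clamps to 255 (in 250-255).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import BandShiftSpec, SegmentationConfig
from .core import CTVolume, Geometry, PhantomSpecError
from .preprocess import RigidTransform, resample

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "verify_bands",
    "LABELS",
]

LABELS = {"background": 0, "parenchyma": 1, "bone": 2, "collecting_system": 3, "stone": 4}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in voxel index (z, y, x) units."""

    center: tuple
    semi_axes: tuple

    def contains(self, zz, yy, xx) -> np.ndarray:
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    def volume_mm3(self, spacing) -> float:
        az, ay, ax = np.asarray(self.semi_axes, float) * np.asarray(spacing, float)
        return 4.0 / 3.0 * np.pi * az * ay * ax


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder along one index axis (0=z, 1=y, 2=x)."""

    axis: int
    center: tuple          # (z, y, x); the component along `axis` is the midpoint
    radius: float
    half_length: float     # half extent along `axis`; use np.inf for full-grid

    def contains(self, zz, yy, xx) -> np.ndarray:
        coords = (zz, yy, xx)
        c = np.asarray(self.center, float)
        trans = [i for i in range(3) if i != self.axis]
        r2 = (coords[trans[0]] - c[trans[0]]) ** 2 + (coords[trans[1]] - c[trans[1]]) ** 2
        inside = r2 <= self.radius**2
        if np.isfinite(self.half_length):
            inside = inside & (np.abs(coords[self.axis] - c[self.axis]) <= self.half_length)
        return inside


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and misalignment description of the phantom."""

    grid_shape: tuple = (96, 96, 96)
    spacing: tuple = (1.0, 1.0, 1.0)
    hu_background: float = -80.0
    hu_parenchyma: float = 40.0
    hu_bone: float = 300.0
    hu_contrast: float = 450.0
    hu_stone: float = 900.0
    noise_sd: float = 10.0
    kidney: Ellipsoid = Ellipsoid(center=(48, 48, 48), semi_axes=(34, 26, 22))
    bones: tuple = (
        Cylinder(axis=0, center=(48, 48, 12), radius=7.0, half_length=np.inf),
        Cylinder(axis=0, center=(48, 48, 84), radius=7.0, half_length=np.inf),
    )
    pelvis: Ellipsoid = Ellipsoid(center=(48, 48, 48), semi_axes=(12, 9.5, 8.5))
    calyces: tuple = (
        Cylinder(axis=1, center=(48, 62, 48), radius=4.0, half_length=10.0),
        Cylinder(axis=1, center=(48, 34, 48), radius=4.0, half_length=10.0),
        Cylinder(axis=0, center=(62, 48, 48), radius=4.0, half_length=12.0),
    )
    stones: tuple = (Ellipsoid(center=(48, 48, 48), semi_axes=(9, 7, 6)),)
    misalignment: RigidTransform = field(
        default_factory=lambda: RigidTransform(
            rotation=(np.deg2rad(1.0), 0.0, 0.0),
            translation=(1.0, -1.5, 2.0),
            center=(47.5, 47.5, 47.5),
        )
    )
    seed: int = 42

    def scaled(self, factor: float) -> "PhantomSpec":
        """Same physical phantom at ``factor``-times finer voxels (same extent)."""
        def sc_e(e: Ellipsoid) -> Ellipsoid:
            return Ellipsoid(
                center=tuple(c * factor for c in e.center),
                semi_axes=tuple(a * factor for a in e.semi_axes),
            )

        def sc_c(c: Cylinder) -> Cylinder:
            return Cylinder(
                axis=c.axis,
                center=tuple(v * factor for v in c.center),
                radius=c.radius * factor,
                half_length=c.half_length * factor,
            )

        return replace(
            self,
            grid_shape=tuple(int(round(n * factor)) for n in self.grid_shape),
            spacing=tuple(s / factor for s in self.spacing),
            kidney=sc_e(self.kidney),
            bones=tuple(sc_c(c) for c in self.bones),
            pelvis=sc_e(self.pelvis),
            calyces=tuple(sc_c(c) for c in self.calyces),
            stones=tuple(sc_e(e) for e in self.stones),
        )


@dataclass
class PhantomGroundTruth:
    """Label map plus analytic/reference volumes and the true misalignment.

    ``misalignment`` is the transform :func:`renalseg.preprocess.coregister`
    should recover (the fixed-to-moving resampling transform).
    ``collecting_system_volume_mm3`` is the volume of the whole cavity
    (pelvis plus calyces, stone space included — the union PSV convention),
    estimated by 3x-per-axis supersampled occupancy.
    """

    labels: np.ndarray
    geometry: Geometry
    stone_volume_mm3: float
    collecting_system_volume_mm3: float
    misalignment: RigidTransform

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def _label_map(spec: PhantomSpec, supersample: int = 1) -> np.ndarray:
    shape = tuple(n * supersample for n in spec.grid_shape)
    # sample positions expressed in base-grid index units
    axes = [(np.arange(n) + 0.5) / supersample - 0.5 for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)

    def full(mask):
        return np.broadcast_to(mask, shape)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[full(spec.kidney.contains(zz, yy, xx))] = LABELS["parenchyma"]
    for bone in spec.bones:
        labels[full(bone.contains(zz, yy, xx))] = LABELS["bone"]
    cavity = full(spec.pelvis.contains(zz, yy, xx)).copy()
    for calyx in spec.calyces:
        cavity |= full(calyx.contains(zz, yy, xx))
    labels[cavity] = LABELS["collecting_system"]
    for stone in spec.stones:
        labels[full(stone.contains(zz, yy, xx))] = LABELS["stone"]
    return labels


def _validate_bands(spec: PhantomSpec,
                    shift: BandShiftSpec,
                    config: SegmentationConfig) -> list:
    f = shift.apply
    checks = [
        ("parenchyma", float(f(spec.hu_parenchyma)), "below skeleton-native band",
         float(f(spec.hu_parenchyma)) < config.skeleton_native_lower),
        ("bone", float(f(spec.hu_bone)), "inside skeleton-native band",
         config.skeleton_native_lower <= float(f(spec.hu_bone)) <= config.skeleton_native_upper),
        ("bone", float(f(spec.hu_bone)), "inside skeleton-delayed band",
         config.skeleton_delayed_lower <= float(f(spec.hu_bone)) <= config.skeleton_delayed_upper),
        ("contrast", float(f(spec.hu_contrast)), "inside skeleton-delayed band",
         config.skeleton_delayed_lower <= float(f(spec.hu_contrast)) <= config.skeleton_delayed_upper),
        ("contrast", float(f(spec.hu_contrast)), "above skeleton-native band",
         float(f(spec.hu_contrast)) > config.skeleton_native_upper),
        ("stone", float(f(spec.hu_stone)), "inside calculus band",
         config.calculus_lower <= float(f(spec.hu_stone)) <= config.calculus_upper),
        ("background", float(f(spec.hu_background)), "below skeleton-native band",
         float(f(spec.hu_background)) < config.skeleton_native_lower),
    ]
    return [
        {"tissue": t, "shifted_mean": v, "requirement": req, "passed": ok}
        for t, v, req, ok in checks
    ]


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[CTVolume, CTVolume, PhantomGroundTruth]:
    """Build the (native, delayed, truth) triple for a phantom spec.

    Native phase: per-label HU means plus seeded Gaussian noise.  Delayed
    phase: same anatomy with the collecting-system cavity at the contrast
    mean and fresh noise, resampled through the inverse of the recoverable
    misalignment (so registration should recover ``truth.misalignment``).
    Deterministic for a fixed seed.
    """
    if spec is None:
        spec = PhantomSpec()

    failures = [c for c in _validate_bands(spec, BandShiftSpec(), SegmentationConfig())
                if not c["passed"]]
    if failures:
        msg = "; ".join(f"{c['tissue']} (shifted mean {c['shifted_mean']:.1f}) "
                        f"violates: {c['requirement']}" for c in failures)
        raise PhantomSpecError(f"phantom intensity bands inconsistent: {msg}")
    for stone in spec.stones:
        corner = np.abs(np.asarray(stone.center) - np.asarray(spec.pelvis.center))
        if np.any(corner + np.asarray(stone.semi_axes) > np.asarray(spec.pelvis.semi_axes)):
            raise PhantomSpecError("stone ellipsoid not contained in the pelvis")

    labels = _label_map(spec)
    geometry = Geometry.default(spacing=spec.spacing)

    hu_by_label = np.array([
        spec.hu_background, spec.hu_parenchyma, spec.hu_bone,
        spec.hu_parenchyma,  # collecting system is urine/soft-tissue-like when unenhanced
        spec.hu_stone,
    ])
    hu_by_label_delayed = hu_by_label.copy()
    hu_by_label_delayed[LABELS["collecting_system"]] = spec.hu_contrast

    rng = np.random.default_rng(spec.seed)
    native_vox = hu_by_label[labels] + rng.normal(0.0, spec.noise_sd, labels.shape)
    delayed_clean = hu_by_label_delayed[labels] + rng.normal(0.0, spec.noise_sd, labels.shape)

    native = CTVolume(voxels=native_vox, geometry=geometry, phase="native")
    delayed_aligned = CTVolume(voxels=delayed_clean, geometry=geometry, phase="delayed")
    generation_transform = spec.misalignment.inverse()
    delayed = resample(delayed_aligned, generation_transform, delayed_aligned,
                       background=spec.hu_background)

    fine = _label_map(spec, supersample=3)
    voxel_sub = geometry.voxel_volume_mm3 / 27.0
    cs_volume = float(np.count_nonzero(
        (fine == LABELS["collecting_system"]) | (fine == LABELS["stone"])
    )) * voxel_sub
    stone_volume = sum(s.volume_mm3(spec.spacing) for s in spec.stones)

    truth = PhantomGroundTruth(
        labels=labels,
        geometry=geometry,
        stone_volume_mm3=stone_volume,
        collecting_system_volume_mm3=cs_volume,
        misalignment=spec.misalignment,
    )
    return native, delayed, truth


def verify_bands(
    spec: PhantomSpec | None = None,
    shift: BandShiftSpec | None = None,
    config: SegmentationConfig | None = None,
) -> dict:
    """Audit each tissue's post-shift mean against its intended threshold band.

    For every check the report also carries the Gaussian probability mass
    (given ``spec.noise_sd``) that a voxel of that tissue falls inside the
    band it is checked against; with zero noise the masses are exactly 0/1.
    """
    from scipy import stats

    spec = spec or PhantomSpec()
    shift = shift or BandShiftSpec()
    config = config or SegmentationConfig()

    bands = {
        "below skeleton-native band": (-np.inf, config.skeleton_native_lower),
        "inside skeleton-native band": (config.skeleton_native_lower,
                                        config.skeleton_native_upper),
        "inside skeleton-delayed band": (config.skeleton_delayed_lower,
                                         config.skeleton_delayed_upper),
        "above skeleton-native band": (config.skeleton_native_upper, np.inf),
        "inside calculus band": (config.calculus_lower, config.calculus_upper),
    }
    hu_means = {
        "parenchyma": spec.hu_parenchyma, "bone": spec.hu_bone,
        "contrast": spec.hu_contrast, "stone": spec.hu_stone,
        "background": spec.hu_background,
    }
    scale = (shift.output_high - shift.output_low) / (shift.input_high - shift.input_low)
    shifted_sd = spec.noise_sd * scale

    checks = _validate_bands(spec, shift, config)
    for check in checks:
        lo, hi = bands[check["requirement"]]
        hu_mean = hu_means[check["tissue"]]
        if shifted_sd == 0:
            mass = 1.0 if lo <= check["shifted_mean"] <= hi else 0.0
        else:
            # mass computed pre-clamp on the HU scale mapped through f
            dist = stats.norm(loc=hu_mean, scale=spec.noise_sd)
            lo_hu = shift.invert(max(lo, shift.output_low)) if np.isfinite(lo) else -np.inf
            hi_hu = shift.invert(min(hi, shift.output_high)) if np.isfinite(hi) else np.inf
            if hi >= shift.output_high:   # clamped top edge is inclusive
                hi_hu = np.inf
            if lo <= shift.output_low:
                lo_hu = -np.inf
            mass = float(dist.cdf(hi_hu) - dist.cdf(lo_hu))
        check["band_probability_mass"] = mass
    return {"checks": checks, "passed": all(c["passed"] for c in checks)}
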