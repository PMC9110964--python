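"""Preprocessing: intensity band shift, median denoising, rigid co-registration.

The preprocessing order is: shift both phases to the 0-255 display band,
median-denoise, then co-register the delayed (moving) phase onto the native
(fixed) grid by maximising Mattes-style mutual information under a rigid
transform, and resample with trilinear interpolation.

Registration is implemented here directly: a Parzen/partial-volume joint
histogram gives a smooth mutual-information metric, optimised by Powell's
method over the six rigid parameters at two resolution levels.  The metric
is fully deterministic (dense strided sampling; the recorded seed only
selects the sample subset for very large volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .config import BandShiftSpec, PreprocessSettings
from .core import (
    CTVolume,
    DomainError,
    Geometry,
    RegistrationError,
)

__all__ = [
    "band_shift",
    "median_denoise",
    "RigidTransform",
    "RegistrationResult",
    "resample",
    "coregister",
]

_J = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)


# ---------------------------------------------------------------------------
# Intensity operations
# ---------------------------------------------------------------------------

def band_shift(volume: CTVolume, spec: BandShiftSpec | None = None) -> CTVolume:
    """Map the HU band [input_low, input_high] linearly onto [output_low, output_high].

    Values outside the input band are clamped to the output edges.  The
    result keeps continuous values (no 8-bit rounding) and is tagged
    ``intensity_domain="shifted"``.
    """
    if spec is None:
        spec = BandShiftSpec()
    if volume.intensity_domain != "hounsfield":
        raise DomainError("band_shift expects a Hounsfield-domain volume")
    return volume.with_voxels(spec.apply(volume.voxels), intensity_domain="shifted")


def median_denoise(volume: CTVolume, radius: int = 1) -> CTVolume:
    """Median filter over the (2*radius+1)^3 neighbourhood, edge-replicated borders."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    filtered = ndimage.median_filter(volume.voxels, size=size, mode="nearest")
    return volume.with_voxels(filtered)


# ---------------------------------------------------------------------------
# Rigid transform
# ---------------------------------------------------------------------------

def _rotation_matrix_zyx(rotation) -> np.ndarray:
    """Rotation matrix acting on (z, y, x)-ordered physical vectors.

    ``rotation`` holds angles (radians) about the physical z, y and x axes,
    composed as R = Rz @ Ry @ Rx in conventional xyz coordinates.
    """
    rz, ry, rx = [float(a) for a in rotation]
    cz, sz = np.cos(rz), np.sin(rz)
    cy, sy = np.cos(ry), np.sin(ry)
    cx, sx = np.cos(rx), np.sin(rx)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    r_xyz = Rz @ Ry @ Rx
    return _J @ r_xyz @ _J


def _euler_from_matrix_zyx(r_zyx: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_rotation_matrix_zyx` (angles about z, y, x)."""
    r = _J @ r_zyx @ _J  # back to xyz representation
    ry = -np.arcsin(np.clip(r[2, 0], -1.0, 1.0))
    rx = np.arctan2(r[2, 1], r[2, 2])
    rz = np.arctan2(r[1, 0], r[0, 0])
    return np.array([rz, ry, rx])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map T(p) = R (p - center) + center + translation.

    All vectors are (z, y, x)-ordered physical mm; ``rotation`` holds the
    angles (radians) about the physical z, y and x axes.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))

    @property
    def matrix(self) -> np.ndarray:
        return _rotation_matrix_zyx(self.rotation)

    @property
    def offset(self) -> np.ndarray:
        """b such that T(p) = matrix @ p + b."""
        r = self.matrix
        return self.center + self.translation - r @ self.center

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (self.matrix @ p.T).T + self.offset

    def inverse(self) -> "RigidTransform":
        r_inv = self.matrix.T
        return RigidTransform(
            rotation=_euler_from_matrix_zyx(r_inv),
            translation=-(r_inv @ self.translation),
            center=self.center,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass
class RegistrationResult:
    """Outcome of :func:`coregister`.

    ``final_metric`` is the *negated* mutual information at the optimum
    (lower is better — the value the optimiser minimised).
    """

    transform: RigidTransform
    final_metric: float
    iterations_run: int
    converged: bool
    seed: int = 0


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _index_affine(transform: RigidTransform, reference: Geometry, moving: Geometry):
    """Affine (M, v) with moving_index = M @ reference_index + v."""
    a = transform.matrix
    b = transform.offset
    d_r = reference.direction * reference.spacing[np.newaxis, :]
    d_m_inv = (moving.direction / moving.spacing[:, np.newaxis]).T  # S^-1 D^T
    m = d_m_inv @ a @ d_r
    v = d_m_inv @ (a @ reference.origin + b - moving.origin)
    return m, v


def resample(
    moving: CTVolume,
    transform: RigidTransform,
    reference: CTVolume,
    background: float | None = None,
) -> CTVolume:
    """Resample ``moving`` onto the reference grid through ``transform``.

    Each reference voxel centre p is mapped to T(p) and the moving volume is
    trilinearly interpolated there; out-of-field voxels take ``background``
    (default: -548 HU in the Hounsfield domain, 0 in the shifted domain).
    """
    if background is None:
        background = 0.0 if moving.intensity_domain == "shifted" else -548.0
    m, v = _index_affine(transform, reference.geometry, moving.geometry)
    out = ndimage.affine_transform(
        np.asarray(moving.voxels, dtype=float),
        matrix=m,
        offset=v,
        output_shape=reference.shape,
        order=1,
        mode="constant",
        cval=background,
        prefilter=False,
    )
    return CTVolume(
        voxels=out,
        geometry=reference.geometry,
        phase=moving.phase,
        intensity_domain=moving.intensity_domain,
    )


# ---------------------------------------------------------------------------
# Mutual-information registration
# ---------------------------------------------------------------------------

def _neg_mutual_information(fvals, mvals, bins, f_range, m_range) -> float:
    """Negative MI with partial-volume (linear) binning on both axes."""
    f_lo, f_hi = f_range
    m_lo, m_hi = m_range
    fi = np.clip((fvals - f_lo) / max(f_hi - f_lo, 1e-12), 0.0, 1.0) * (bins - 1)
    mi_ = np.clip((mvals - m_lo) / max(m_hi - m_lo, 1e-12), 0.0, 1.0) * (bins - 1)
    i0 = np.floor(fi).astype(np.intp)
    j0 = np.floor(mi_).astype(np.intp)
    wi = fi - i0
    wj = mi_ - j0
    i1 = np.minimum(i0 + 1, bins - 1)
    j1 = np.minimum(j0 + 1, bins - 1)
    hist = np.zeros((bins, bins))
    np.add.at(hist, (i0, j0), (1 - wi) * (1 - wj))
    np.add.at(hist, (i0, j1), (1 - wi) * wj)
    np.add.at(hist, (i1, j0), wi * (1 - wj))
    np.add.at(hist, (i1, j1), wi * wj)
    total = hist.sum()
    if total <= 0:
        return 0.0
    p = hist / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
    return -mi


def _downsample(volume: CTVolume, factor: int) -> CTVolume:
    if factor == 1:
        return volume
    smoothed = ndimage.gaussian_filter(np.asarray(volume.voxels, float), sigma=factor / 2.0)
    sub = smoothed[::factor, ::factor, ::factor]
    geom = Geometry(
        spacing=volume.spacing * factor,
        origin=volume.origin,
        direction=volume.direction,
    )
    return CTVolume(voxels=np.clip(sub, volume.voxels.min(), volume.voxels.max()),
                    geometry=geom, phase=volume.phase,
                    intensity_domain=volume.intensity_domain)


def _physical_bounds(volume: CTVolume) -> tuple:
    shape = np.array(volume.shape) - 1
    corners = np.array(
        [[z, y, x] for z in (0, shape[0]) for y in (0, shape[1]) for x in (0, shape[2])],
        dtype=float,
    )
    phys = volume.geometry.index_to_physical(corners)
    return phys.min(axis=0), phys.max(axis=0)


class _MetricEvaluator:
    """Evaluates negative MI for a parameter vector on one resolution level."""

    def __init__(self, fixed: CTVolume, moving: CTVolume, center, bins: int,
                 stride: int = 1, max_samples: int = 200_000, seed: int = 0):
        rng = np.random.default_rng(seed)
        idx = np.stack(
            np.meshgrid(*[np.arange(0, n, stride) for n in fixed.shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3).astype(float)
        if len(idx) > max_samples:
            keep = rng.choice(len(idx), size=max_samples, replace=False)
            keep.sort()
            idx = idx[keep]
        # jitter sample positions off the voxel grid so interpolation smoothing
        # is uniform across candidate transforms (suppresses the grid artifact
        # that otherwise biases MI toward slightly misaligned optima)
        idx += rng.uniform(-0.5, 0.5, idx.shape)
        idx = np.clip(idx, 0.0, np.asarray(fixed.shape, float) - 1.0)
        fvals = ndimage.map_coordinates(
            np.asarray(fixed.voxels, float), idx.T, order=1, mode="nearest"
        )
        self.fvals = fvals
        self.points = fixed.geometry.index_to_physical(idx)
        self.moving = moving
        self.mov_arr = np.asarray(moving.voxels, float)
        self.center = np.asarray(center, float)
        self.bins = bins
        self.f_range = (float(fvals.min()), float(fvals.max()))
        self.m_range = (float(self.mov_arr.min()), float(self.mov_arr.max()))
        self.n_evaluations = 0

    def __call__(self, params) -> float:
        t = RigidTransform(rotation=params[:3], translation=params[3:], center=self.center)
        q = t.apply(self.points)
        mov_idx = self.moving.geometry.physical_to_index(q)
        mvals = ndimage.map_coordinates(
            self.mov_arr, mov_idx.T, order=1, mode="constant", cval=np.nan
        )
        valid = np.isfinite(mvals)
        self.n_evaluations += 1
        if valid.sum() < 16:
            return 0.0  # essentially no overlap: flat, worst metric
        return _neg_mutual_information(
            self.fvals[valid], mvals[valid], self.bins, self.f_range, self.m_range
        )


def coregister(
    fixed: CTVolume,
    moving: CTVolume,
    settings: PreprocessSettings | None = None,
    initial: RigidTransform | None = None,
) -> RegistrationResult:
    """Recover the rigid transform mapping fixed-space points into the moving volume.

    Maximises mutual information between the fixed volume and the moving
    volume resampled through the transform (linear interpolation), using
    Powell's method over (rz, ry, rx, tz, ty, tx) at
    ``settings.registration_levels`` resolution levels.  Deterministic for a
    fixed ``settings.registration_seed``.

    Raises :class:`RegistrationError` if the volumes do not overlap
    physically; non-convergence is reported via ``converged=False``.
    """
    if settings is None:
        settings = PreprocessSettings()
    if fixed.intensity_domain != moving.intensity_domain:
        raise DomainError("fixed and moving volumes must share an intensity domain")

    lo_f, hi_f = _physical_bounds(fixed)
    lo_m, hi_m = _physical_bounds(moving)
    if np.any(hi_f < lo_m) or np.any(hi_m < lo_f):
        raise RegistrationError("fixed and moving volumes do not overlap physically")

    center = fixed.geometry.index_to_physical((np.array(fixed.shape) - 1) / 2.0)
    if initial is not None:
        params = np.concatenate([initial.rotation, initial.translation])
    else:
        params = np.zeros(6)

    factors = [2 ** (settings.registration_levels - 1 - i)
               for i in range(settings.registration_levels)]
    iterations = 0
    converged = True
    final_metric = 0.0
    for level, factor in enumerate(factors):
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)
        stride = 2 if factor == 1 and min(fixed.shape) >= 64 else 1
        evaluator = _MetricEvaluator(
            fx, mv, center, settings.registration_bins,
            stride=stride, seed=settings.registration_seed,
        )
        step = 1.0 if factor == 1 else 2.0
        direc = np.diag([0.02, 0.02, 0.02, step, step, step])
        res = optimize.minimize(
            evaluator,
            params,
            method="Powell",
            options={
                "direc": direc,
                "xtol": 1e-4,
                "ftol": 1e-7,
                "maxiter": settings.registration_max_iterations,
            },
        )
        params = np.asarray(res.x, dtype=float)
        iterations += max(int(res.nit), 1)
        converged = converged and bool(res.success)
        final_metric = float(res.fun)

    transform = RigidTransform(rotation=params[:3], translation=params[3:], center=center)
    return RegistrationResult(
        transform=transform,
        final_metric=final_metric,
        iterations_run=iterations,
        converged=converged,
        seed=settings.registration_seed,
    )
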