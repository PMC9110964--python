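"""Independent brute-force oracles for morphology and median filtering.

Two tiers:

* ``loop_*`` — pure-Python triple loops over voxels and structuring-element
  offsets; the definitional reference, usable only on tiny grids.
* ``shift_*`` — enumeration over structuring-element offsets using padded
  array shifts; independent of scipy's correlation-based machinery and fast
  enough for hundreds of masks up to 10^3 voxels.

Offsets for a cube of edge d are ``arange(d) - d//2`` per axis.  Erosion:
out[i] = all(input[i + o]); dilation: out[i] = any(input[i - o]); the grid
exterior is background for both.
"""

import itertools

import numpy as np


def cube_offsets(dim: int):
    axis = np.arange(dim) - dim // 2
    return list(itertools.product(axis, axis, axis))


# ---------------------------------------------------------------------------
# Pure-loop tier
# ---------------------------------------------------------------------------

def _inside(shape, idx):
    return all(0 <= idx[a] < shape[a] for a in range(3))


def loop_erode(bits: np.ndarray, dim: int) -> np.ndarray:
    offs = cube_offsets(dim)
    out = np.zeros_like(bits, dtype=bool)
    for z in range(bits.shape[0]):
        for y in range(bits.shape[1]):
            for x in range(bits.shape[2]):
                ok = True
                for oz, oy, ox in offs:
                    j = (z + oz, y + oy, x + ox)
                    if not (_inside(bits.shape, j) and bits[j]):
                        ok = False
                        break
                out[z, y, x] = ok
    return out


def loop_dilate(bits: np.ndarray, dim: int) -> np.ndarray:
    offs = cube_offsets(dim)
    out = np.zeros_like(bits, dtype=bool)
    for z in range(bits.shape[0]):
        for y in range(bits.shape[1]):
            for x in range(bits.shape[2]):
                hit = False
                for oz, oy, ox in offs:
                    j = (z - oz, y - oy, x - ox)
                    if _inside(bits.shape, j) and bits[j]:
                        hit = True
                        break
                out[z, y, x] = hit
    return out


def loop_median(arr: np.ndarray, radius: int) -> np.ndarray:
    """Median over the (2r+1)^3 neighbourhood with edge replication."""
    out = np.empty_like(arr, dtype=float)
    n = arr.shape
    for z in range(n[0]):
        for y in range(n[1]):
            for x in range(n[2]):
                vals = []
                for oz in range(-radius, radius + 1):
                    for oy in range(-radius, radius + 1):
                        for ox in range(-radius, radius + 1):
                            j = (
                                min(max(z + oz, 0), n[0] - 1),
                                min(max(y + oy, 0), n[1] - 1),
                                min(max(x + ox, 0), n[2] - 1),
                            )
                            vals.append(arr[j])
                out[z, y, x] = np.median(vals)
    return out


# ---------------------------------------------------------------------------
# Shift-enumeration tier
# ---------------------------------------------------------------------------

def _shifted(bits: np.ndarray, off) -> np.ndarray:
    """bits sampled at index + off, exterior False."""
    pad = max(abs(int(o)) for o in off) if any(off) else 0
    if pad == 0:
        return bits
    padded = np.pad(bits, pad, constant_values=False)
    sl = tuple(slice(pad + int(o), pad + int(o) + n) for o, n in zip(off, bits.shape))
    return padded[sl]


def shift_erode(bits: np.ndarray, dim: int) -> np.ndarray:
    out = np.ones_like(bits, dtype=bool)
    for off in cube_offsets(dim):
        out &= _shifted(bits, off)
    return out


def shift_dilate(bits: np.ndarray, dim: int) -> np.ndarray:
    out = np.zeros_like(bits, dtype=bool)
    for off in cube_offsets(dim):
        out |= _shifted(bits, tuple(-o for o in off))
    return out


def shift_opening(bits: np.ndarray, dim: int) -> np.ndarray:
    return shift_dilate(shift_erode(bits, dim), dim)


def shift_closing(bits: np.ndarray, dim: int) -> np.ndarray:
    return shift_erode(shift_dilate(bits, dim), dim)


def shift_particle_removal(bits: np.ndarray, dim: int) -> np.ndarray:
    return shift_closing(shift_opening(bits, dim), dim)
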