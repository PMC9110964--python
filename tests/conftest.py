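import dataclasses

import numpy as np
import pytest

from renalseg.core import BinaryMask, CTVolume, Geometry
from renalseg.phantom import PhantomSpec, generate_phantom
from renalseg.preprocess import RigidTransform
from renalseg.segmentation import run_full_pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """The default 96^3 phantom (seed 42) with ground truth."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    """One full pipeline run on the default phantom, shared across tests."""
    native, delayed, _ = default_phantom
    return run_full_pipeline(native, delayed)


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 32^3 phantom (same physical anatomy at 3 mm voxels)."""
    return generate_phantom(dataclasses.replace(PhantomSpec(seed=7).scaled(1 / 3)))


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Noise-free, perfectly aligned 32^3 phantom for exact-value tests."""
    spec = dataclasses.replace(
        PhantomSpec(seed=7).scaled(1 / 3),
        noise_sd=0.0,
        misalignment=RigidTransform(center=(46.5, 46.5, 46.5)),
    )
    return generate_phantom(spec)


@pytest.fixture
def unit_geometry():
    return Geometry.default()


def make_volume(values, spacing=(1.0, 1.0, 1.0), domain="shifted", phase="native"):
    """Small helper to wrap a 3D array as a CTVolume."""
    arr = np.asarray(values, dtype=float)
    return CTVolume(
        voxels=arr,
        geometry=Geometry.default(spacing=spacing),
        phase=phase,
        intensity_domain=domain,
    )


def make_mask(bits, spacing=(1.0, 1.0, 1.0), label=""):
    return BinaryMask(
        bits=np.asarray(bits, dtype=bool),
        geometry=Geometry.default(spacing=spacing),
        label=label,
    )
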