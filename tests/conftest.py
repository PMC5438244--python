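"""Shared fixtures: small synthetic volumes and one session-wide phantom."""

import numpy as np
import pytest

from ctperf.core import ImageVolume
from ctperf.phantom import PhantomSpec, generate_series


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ImageVolume(np.asarray(voxels, dtype=float), spacing, origin)


@pytest.fixture(scope="session")
def default_phantom():
    """Default study conditions, seed 0 (normal lungs, 5 HU noise)."""
    spec = PhantomSpec(seed=0)
    scans, truth = generate_series(spec)
    return spec, scans, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(seed=0, noise_sd=0.0)
    scans, truth = generate_series(spec)
    return spec, scans, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
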