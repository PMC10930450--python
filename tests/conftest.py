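import dataclasses

import numpy as np
import pytest

import pervimap as pm
from pervimap.geometry import ReferenceGrid


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    voxels = np.asarray(voxels, dtype=float)
    grid = ReferenceGrid(tuple(voxels.shape), tuple(spacing), tuple(origin))
    return pm.CTVolume(voxels, grid, **kw)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size (96^3) phantom patient with noise and misalignment."""
    return pm.generate_patient(pm.PhantomSpec(seed=11), "phantom-default")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, perfectly aligned phantom (closed-form truth applies)."""
    spec = dataclasses.replace(pm.PhantomSpec(seed=11), noise_sd_hu=0.0, misalignment=None)
    return pm.generate_patient(spec, "phantom-clean")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240305)
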