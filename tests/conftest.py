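import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dwiqc.artifact_sim import PhantomSpec, make_phantom_volume
from dwiqc.io_slicing import SliceSample, compute_brain_extent


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(seed=3)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """One default noisy phantom volume shared across tests."""
    return make_phantom_volume(phantom_spec, volume_id="phantom")


@pytest.fixture(scope="session")
def phantom_extent(phantom):
    return compute_brain_extent(phantom)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, jitter-free, texture-free phantom for exact-value checks."""
    spec = PhantomSpec(seed=0, noise_sigma=0.0, geometry_jitter=0.0,
                       texture_amplitude=0.0, bias_amplitude=0.0)
    return make_phantom_volume(spec, volume_id="clean")


def random_slice(shape=(48, 52), seed=0, view="axial", label=None):
    rng = np.random.default_rng(seed)
    return SliceSample(rng.random(shape), view, "vol", 0, 0, label=label)
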