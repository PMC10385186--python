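import numpy as np
import pytest

from tracergan.phantom import PhantomParams, make_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def inversion_pair():
    """Zero-noise phantom where FDG = 1 - FBB inside the brain mask."""
    params = PhantomParams(noise_sd_fbb=0.0, noise_sd_fdg=0.0,
                           anticorrelation_gain=1.0,
                           anticorrelation_offset=1.0,
                           smoothing_sigma_voxels=0.0, seed=7)
    return make_phantom_pair(params), params


@pytest.fixture(scope="session")
def default_pair():
    params = PhantomParams(seed=11)
    return make_phantom_pair(params), params
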