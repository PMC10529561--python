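import numpy as np
import pytest

from ctdenoise import NoiseSpec, PhantomSpec, add_gaussian_noise, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20230927)


@pytest.fixture
def random_image(rng):
    return rng.random((32, 32))


@pytest.fixture
def phantom():
    return generate_phantom(PhantomSpec(height=96, width=96, seed=11))


@pytest.fixture
def noisy_phantom(phantom):
    return add_gaussian_noise(phantom, NoiseSpec(sigma8=20, seed=11))
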