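import numpy as np
import pytest

from srsphasor.synth_phantom import (
    NoiseModel,
    default_axis,
    default_library,
    default_phantom_config,
    generate_phantom,
)


@pytest.fixture(scope="session")
def axis40():
    """The study acquisition axis: 2800-3050 cm^-1, 40 channels."""
    return default_axis()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default geometry rendered without noise (exact spectra per class)."""
    cfg = default_phantom_config(123, noise=NoiseModel(0, 0))
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom at the default shot-noise level."""
    return generate_phantom(default_phantom_config(123))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
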