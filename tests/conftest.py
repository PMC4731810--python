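import numpy as np
import pytest

from nestcamo import fit_default_mapper, generate_spectra
from nestcamo.vision import DEFAULT_GRID, builtin_visual_system


@pytest.fixture(scope="session")
def spectral_library():
    return generate_spectra(200, seed=11)


@pytest.fixture(scope="session")
def ferret_system():
    return builtin_visual_system("ferret")


@pytest.fixture(scope="session")
def ferret_mapper(ferret_system):
    return fit_default_mapper(ferret_system, seed=0)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
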