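import numpy as np
import pytest

from serialoct import optics, phantom


@pytest.fixture(scope="session")
def laser() -> optics.LaserSpec:
    return optics.LaserSpec()


@pytest.fixture(scope="session")
def tile_spec() -> optics.TileSpec:
    return optics.TileSpec()


@pytest.fixture(scope="session")
def brain_phantom() -> phantom.Phantom:
    """Default digital tissue block shared across the suite (1.2 x 1.2 x 0.8 mm)."""
    return phantom.make_phantom(seed=7)


@pytest.fixture(scope="session")
def small_phantom() -> phantom.Phantom:
    return phantom.make_phantom(shape=(48, 48, 32), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
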