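import numpy as np
import pytest

from onhcmap import (
    DiscLocation,
    SimParams,
    build_30_2_grid,
    build_hex_array,
)


@pytest.fixture(scope="session")
def hex_array():
    return build_hex_array("right")


@pytest.fixture(scope="session")
def grid():
    return build_30_2_grid("right")


@pytest.fixture(scope="session")
def disc():
    return DiscLocation()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_params():
    """Deterministic simulator settings: no noise, no between-subject gain."""
    return SimParams(noise_sd=0.0, td_noise_sd=0.0, subject_gain_sigma=0.0,
                     geometry_jitter=False)
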