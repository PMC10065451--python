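import numpy as np
import pytest

from llsheet import OpticalConfig, make_grids


@pytest.fixture(scope="session")
def config():
    """Reference instrument frame: 488/520 nm, water, NA_det 1.0."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def grids(config):
    """Default production grid (1001 samples, 2.6 NA span)."""
    return make_grids(config)


@pytest.fixture(scope="session")
def grids_small(config):
    """Coarse grid for fast unit tests."""
    return make_grids(config, na_span=2.6, n_k=301)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
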