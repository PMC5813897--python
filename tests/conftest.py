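import numpy as np
import pytest

import iirabm as m
from iirabm.params import ModelParams, RuleConstants


@pytest.fixture
def tiny_constants():
    """A 15x15 profile small enough for per-test simulation."""
    return m.SMALL_CONSTANTS.replace(grid_shape=(15, 15))


@pytest.fixture
def tiny_params():
    return ModelParams(injury_radius=4)


@pytest.fixture
def tiny_world(tiny_params, tiny_constants):
    return m.init_world(tiny_params, seed=7, constants=tiny_constants)


@pytest.fixture
def small_world():
    """The desk-scale 25x25 reference configuration."""
    return m.init_world(m.SMALL_REFERENCE_PARAMS, seed=3, constants=m.SMALL_CONSTANTS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
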