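import numpy as np
import pytest

from nmmforest import ParameterSpace, latin_hypercube
from nmmforest.model import simulate_batch


@pytest.fixture(scope="session")
def space():
    return ParameterSpace()


@pytest.fixture(scope="session")
def small_lhs_batch(space):
    """64 LHS draws integrated once, shared by feature/structure tests."""
    design = latin_hypercube(64, space, seed=101)
    times, outputs, divergent = simulate_batch(design.to_numpy())
    return design, times, outputs, divergent


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
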