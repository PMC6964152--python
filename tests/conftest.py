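import numpy as np
import pytest

from ctdl.envs.gridworld import GridWorld


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_world():
    """Hand-built 4x4 world: start bottom-left, goal top-right, one hazard."""
    return GridWorld(4, 4, frozenset({(1, 2), (2, 1)}), (3, 3), (0, 0))


@pytest.fixture
def empty_world():
    """4x4 world with no negative cells."""
    return GridWorld(4, 4, frozenset(), (3, 3), (0, 0))
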