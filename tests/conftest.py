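import numpy as np
import pytest

import crowdperc as cp


@pytest.fixture(scope="session")
def dense_matrix():
    """A phi = 0.21 RSA matrix (the rate-analysis density)."""
    return cp.generate_matrix(0.21, 50.0, seed=1)


@pytest.fixture(scope="session")
def dense_network(dense_matrix):
    return cp.tessellate(dense_matrix)


@pytest.fixture(scope="session")
def dilute_matrix():
    return cp.generate_matrix(0.06, 50.0, seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gate_matrix():
    """Two close 'gate' obstacles (impassable channel) flanked by two far ones.

    The channel between the gate pair has centre distance 1.9 < 2 sigma, so
    a tracer may not cross it however large the jump.
    """
    pos = np.array([[5.0, 4.05], [5.0, 5.95], [2.0, 5.0], [8.0, 5.0]])
    return cp.ObstacleMatrix(pos, L=10.0, sigma=1.0, seed=7)


@pytest.fixture(scope="session")
def gate_network(gate_matrix):
    return cp.tessellate(gate_matrix)
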