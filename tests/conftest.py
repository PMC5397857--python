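import numpy as np
import pytest

from netphase import Network, SimConfig


@pytest.fixture
def star_network() -> Network:
    """Unweighted star: hub node 0 with 4 leaves."""
    A = np.zeros((5, 5))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return Network(A)


@pytest.fixture
def triangle_half() -> Network:
    """Weighted triangle with all weights 0.5."""
    A = np.full((3, 3), 0.5)
    np.fill_diagonal(A, 0.0)
    return Network(A)


@pytest.fixture
def complete_network() -> Network:
    A = np.ones((20, 20))
    np.fill_diagonal(A, 0.0)
    return Network(A)


@pytest.fixture
def two_class_network() -> Network:
    """Two degree classes: 4 hubs wired to everyone, 12 leaves wired to hubs.

    Hubs have degree 15, leaves degree 4; every node has at least one
    connection into the strongly synchronised hub core.
    """
    n_hub, n_leaf = 4, 12
    n = n_hub + n_leaf
    A = np.zeros((n, n))
    A[:n_hub, :] = 1.0
    A[:, :n_hub] = 1.0
    np.fill_diagonal(A, 0.0)
    return Network(A)


@pytest.fixture
def quiet_config() -> SimConfig:
    """Deterministic short simulation config for unit tests."""
    return SimConfig(
        coupling=5.0,
        noise_sd=0.0,
        duration_s=20.0,
        transient_s=10.0,
        seed=11,
        n_runs=1,
    )
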