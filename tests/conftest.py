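import numpy as np
import pytest

from hetsis import Network, RecoveryRates


@pytest.fixture
def dyad():
    return Network.from_edges(2, [(0, 1)])


@pytest.fixture
def ring4():
    return Network.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def star5():
    """Hub 0 with four leaves (K_{1,4})."""
    return Network.from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def path5():
    return Network.from_edges(5, [(i, i + 1) for i in range(4)])


def ring(n: int) -> Network:
    return Network.from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def complete(n: int) -> Network:
    return Network.from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


def star(n_leaves: int) -> Network:
    return Network.from_edges(n_leaves + 1, [(0, i) for i in range(1, n_leaves + 1)])


def hetero_rates(n: int, seed: int, low: float = 0.3, high: float = 3.0) -> RecoveryRates:
    rng = np.random.default_rng(seed)
    return RecoveryRates(rng.uniform(low, high, n), provenance={"scheme": "test-uniform"})
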