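import numpy as np
import pytest

from hypermodularity import Hypergraph


@pytest.fixture
def toy():
    """Three-edge toy hypergraph on four nodes: {1,2}, {1,2,3}, {2,3,4}."""
    H = Hypergraph(4)
    H.add_edge((0, 1))
    H.add_edge((0, 1, 2))
    H.add_edge((1, 2, 3))
    return H


def random_hypergraph(rng, n_min=3, n_max=8, m_min=2, m_max=12, k_max=4,
                      w_max=3) -> Hypergraph:
    """Small random hypergraph with distinct-node edges and integer weights."""
    n = int(rng.integers(n_min, n_max + 1))
    H = Hypergraph(n)
    for _ in range(int(rng.integers(m_min, m_max + 1))):
        k = int(rng.integers(2, min(k_max, n) + 1))
        nodes = rng.choice(n, size=k, replace=False)
        H.add_edge(nodes, int(rng.integers(1, w_max + 1)))
    return H


def set_partitions(n):
    """All set partitions of range(n) as canonical label vectors."""
    if n == 0:
        yield []
        return
    for part in set_partitions(n - 1):
        top = max(part, default=-1)
        for lab in range(top + 2):
            yield part + [lab]
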