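from __future__ import annotations

import numpy as np
import pytest

from gametenet import new_network


def random_network(rng: np.random.Generator, n_max: int = 60, p: float = 0.15):
    """Random simple graph (possibly disconnected, with isolated nodes)."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"P{i:03d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return new_network(nodes, edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
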