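import numpy as np
import pytest

from evodecode.evolution import build_fully_connected, init_network, mutate
from evodecode.netcore import NetworkGenome


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_small_genome(rng: np.random.Generator, k_units: int = 3) -> NetworkGenome:
    """A structurally varied small genome: minimal init plus random growth."""
    g = init_network(rng, k_units)
    for _ in range(int(rng.integers(0, 8))):
        g = mutate(g, rng, 1.0)
    for c in g.connections:
        c.weight = float(rng.uniform(-0.8, 0.8))
    return g


@pytest.fixture
def full_genome(rng) -> NetworkGenome:
    return build_fully_connected(3, 2, rng)
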