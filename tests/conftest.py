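import numpy as np
import pytest

from grnmod.core import GeneNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20100326)


def random_network(rng: np.random.Generator, n: int = 10, n_edges: int = 20) -> GeneNetwork:
    """Random genotype in founder style: n_edges signed entries."""
    cells = rng.choice(n * n, size=n_edges, replace=False)
    w = np.zeros(n * n, dtype=np.int8)
    w[cells] = np.where(rng.random(n_edges) < 0.5, 1, -1)
    return GeneNetwork(w.reshape(n, n))
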