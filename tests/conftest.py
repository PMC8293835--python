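import numpy as np
import pytest

from micronets import CountMatrix
from tests_helper import bundle_from_sim


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    vals = rng.integers(0, 50, size=(8, 5)).astype(float)
    vals[0, 2] = 0.0
    vals[3, 4] = 0.0
    return CountMatrix(vals, [f"S{i}" for i in range(8)],
                       [f"T{i}" for i in range(5)])


@pytest.fixture
def positive_counts() -> CountMatrix:
    rng = np.random.default_rng(7)
    vals = rng.integers(1, 100, size=(10, 6)).astype(float)
    return CountMatrix(vals, [f"S{i}" for i in range(10)],
                       [f"T{i}" for i in range(6)])


@pytest.fixture
def random_weighted_bundle():
    def make(n: int, p_edge: float, seed: int):
        rng = np.random.default_rng(seed)
        sim = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        edges = rng.random(len(iu[0])) < p_edge
        sim[iu[0][edges], iu[1][edges]] = rng.uniform(0.05, 0.95,
                                                      int(edges.sum()))
        sim = sim + sim.T
        return bundle_from_sim(sim)

    return make
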