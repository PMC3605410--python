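import numpy as np
import pandas as pd
import pytest

import coexdisrupt as cd


@pytest.fixture(scope="session")
def small_bundle():
    """Three 20-transcript modules, 30 samples/condition, no disruption."""
    return cd.simulate_expression_pair(
        n_modules=3,
        module_sizes=(20, 20, 20),
        n_samples_per_condition=30,
        loading=0.8,
        disruption_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def truth_partition(small_bundle):
    return cd.ModulePartition(small_bundle.truth_partition)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_adjacency(rng, n: int) -> cd.AdjacencyNetwork:
    """Random symmetric weighted graph for oracle checks."""
    w = rng.uniform(0, 1, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    ids = pd.Index([f"T{i:03d}" for i in range(n)])
    return cd.AdjacencyNetwork(w, ids, beta=1.0)
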