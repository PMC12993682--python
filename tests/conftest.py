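import numpy as np
import pandas as pd
import pytest

from ecoassembly.data_io import CommunityMatrix, read_newick
from ecoassembly.phylo import cophenetic_distances


@pytest.fixture
def small_tree():
    """Three-tip tree with known patristic distances: AB=2, AC=BC=4."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_dist(small_tree):
    return cophenetic_distances(small_tree)


@pytest.fixture
def rel_matrix():
    df = pd.DataFrame(
        [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.25, 0.25, 0.5]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(df, mode="relative")


@pytest.fixture
def count_matrix():
    df = pd.DataFrame(
        [[5, 5, 0], [0, 5, 5], [2, 3, 5]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(df, mode="pseudocount")


def random_community_instance(rng, max_taxa=12):
    """Random tree + two abundance vectors for oracle equivalence tests."""
    from ecoassembly.synthetic import simulate_yule_tree

    n = int(rng.integers(3, max_taxa + 1))
    tree = simulate_yule_tree(n, seed=rng)
    dm = cophenetic_distances(tree)
    ids = list(dm.ids)

    def draw():
        k = int(rng.integers(1, n + 1))
        chosen = rng.choice(n, size=k, replace=False)
        w = rng.dirichlet(np.ones(k))
        v = np.zeros(n)
        v[chosen] = w
        return pd.Series(v, index=ids)

    return dm, draw(), draw()
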