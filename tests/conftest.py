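import numpy as np
import pytest

from topictree import fit_lda, generate_trajectory
from topictree.tree import CellDistanceMatrix


@pytest.fixture(scope="session")
def small_trajectory():
    """Linear 4-stage trajectory, modest size, shared across tests."""
    cm, truth = generate_trajectory(M=40, V=200, K=3, branches=1,
                                    tokens_per_cell=500, noise=0.1, seed=11)
    return cm, truth


@pytest.fixture(scope="session")
def small_model(small_trajectory):
    cm, _ = small_trajectory
    return fit_lda(cm, 3, sweeps=150, burn_in=60, seed=11)


def random_distance_matrix(n: int, seed: int) -> CellDistanceMatrix:
    """Random euclidean distances between n points in the unit square."""
    from scipy.spatial.distance import pdist, squareform
    rng = np.random.default_rng(seed)
    d = squareform(pdist(rng.random((n, 2))))
    return CellDistanceMatrix(d, [f"c{i}" for i in range(n)])
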