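import numpy as np
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def chain6_params():
    """Chain Ising graph on 6 nodes, couplings 1, thresholds 0."""
    beta = np.zeros((6, 6))
    for i in range(5):
        beta[i, i + 1] = beta[i + 1, i] = 1.0
    return sn.IsingParams(couplings=beta, thresholds=np.zeros(6))


@pytest.fixture(scope="session")
def two_triangles():
    """Two unit-weight triangles joined by one bridge edge (6 nodes)."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
        w[a, b] = w[b, a] = 1.0
    return w


@pytest.fixture(scope="session")
def small_fixture():
    """Small gated occurrence/severity/distress triple (n=400, p=8)."""
    return sn.make_msas_fixture(n=400, p=8, seed=11)


def random_weight_matrix(p: int, rng: np.random.Generator, density: float = 0.4):
    """Random symmetric signed weight matrix with zero diagonal."""
    w = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.1, 1.0, len(iu[0])) * rng.choice([-1, 1], len(iu[0]))
    w[iu] = np.where(mask, vals, 0.0)
    return w + w.T
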