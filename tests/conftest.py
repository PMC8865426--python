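import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from omicsfuse import FeatureMatrix, build_network, make_blobs, replicate_layer


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 samples, 5 features, 3 separable clusters, single layer."""
    return make_blobs(30, 5, 3, 0.5, seed=1)


@pytest.fixture(scope="session")
def two_layer_cohort():
    """Noiseless 2-blob cohort with two identical layers (24 x 10)."""
    c = make_blobs(24, 10, 2, 0.3, seed=2)
    return replicate_layer(c, 2)


@pytest.fixture(scope="session")
def two_layer_network(two_layer_cohort):
    return build_network(two_layer_cohort.layers)


def random_feature_matrix(rng, n=8, p=5, name="layer", missing=0.0):
    v = rng.normal(size=(n, p))
    if missing:
        mask = rng.random((n, p)) < missing
        v[mask] = np.nan
    return FeatureMatrix(
        v,
        [f"s{i}" for i in range(n)],
        [f"f{j}" for j in range(p)],
        name,
    )


def random_network(rng, n=6, t=2, r_mask=0.0):
    """Small random multiplex network with optional random unavailability."""
    from omicsfuse.simnet import MultiplexNetwork, SimilarityLayer

    layers = []
    for k in range(t):
        A = rng.uniform(0.0, 1.0, size=(n, n))
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
        W = np.ones((n, n))
        if r_mask:
            drop = rng.random((n, n)) < r_mask
            drop = np.triu(drop, k=1)
            drop = drop | drop.T
            W[drop] = 0.0
            A = np.where(W > 0, A, np.nan)
        layers.append(SimilarityLayer(A, W, n, 1.0 / n**2, "euclidean-rbf", f"L{k}"))
    return MultiplexNetwork(layers, [f"s{i}" for i in range(n)])
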