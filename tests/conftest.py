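import numpy as np
import pytest

import atlasbench as ab


@pytest.fixture(scope="session")
def small_split():
    """A small simulated split dataset shared by read-only tests."""
    cfg = ab.splat_scenario(scale=0.2, seed=7, n_features=300)
    return ab.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_embedding(small_split):
    return ab.fixture_integrate(small_split, n_pcs=10, removal=1.0, seed=7)


@pytest.fixture()
def toy_matrix():
    """4 cells x 3 features, two batches, two labels."""
    return ab.CellMatrix(
        counts=np.array([[5, 0, 1], [2, 3, 0], [0, 1, 4], [1, 1, 1]], float),
        cell_ids=np.array(["c1", "c2", "c3", "c4"], object),
        feature_ids=np.array(["f1", "f2", "f3"], object),
        batch=np.array(["a", "a", "b", "b"], object),
        label=np.array(["x", "x", "y", "y"], object),
    )


def gaussian_embedding(
    n_per=50, d=4, n_labels=3, sep=20.0, seed=0, query_copy=True
):
    """Well-separated Gaussian label clusters; query resampled or copied."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, (n_labels, d))
    ref = np.vstack([c + rng.normal(0, 1, (n_per, d)) for c in centers])
    labels = np.repeat([f"l{i}" for i in range(n_labels)], n_per).astype(object)
    if query_copy:
        query, qlabels = ref.copy(), labels.copy()
    else:
        query = np.vstack([c + rng.normal(0, 1, (n_per, d)) for c in centers])
        qlabels = labels.copy()
    return ab.JointEmbedding(ref, query), labels, qlabels
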