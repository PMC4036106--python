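import numpy as np
import pytest

import somscape as ss


@pytest.fixture(scope="session")
def small_blobs():
    """Three well-separated Gaussian clusters in 5 dimensions."""
    return ss.make_gaussian_blobs(n_clusters=3, dim=5, n_per_cluster=8, separation=8.0, seed=3)


@pytest.fixture(scope="session")
def small_trained(small_blobs):
    """A trained 12x12 map on the small blob fixture."""
    svd = ss.truncated_svd(small_blobs.matrix, k=3)
    fps = ss.project_fingerprints(small_blobs.matrix, svd)
    trained = ss.train_flsom(fps, 12, 12, svd)
    return svd, fps, trained


@pytest.fixture
def random_lattice():
    def make(seed, rows=5, cols=6, k=3):
        rng = np.random.default_rng(seed)
        return ss.Lattice(rows, cols, rng.normal(size=(rows, cols, k)), k)

    return make
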