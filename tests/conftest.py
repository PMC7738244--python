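import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_embedding(rng):
    """Two well-separated 2-D blobs of 30 points each, with labels."""
    from ndrindex import Embedding

    a = rng.standard_normal((30, 2)) * 0.3 + [0.0, 0.0]
    b = rng.standard_normal((30, 2)) * 0.3 + [12.0, 0.0]
    labels = np.array([0] * 30 + [1] * 30)
    return Embedding(np.vstack([a, b])), labels


@pytest.fixture(scope="session")
def small_counts():
    """A fast planted-cluster count matrix for selection-level tests."""
    from ndrindex import ScSimSpec, simulate_counts

    spec = ScSimSpec(
        n_cells=80,
        n_genes=200,
        k_clusters=3,
        markers_per_cluster=30,
        dropout_target=0.85,
        seed=7,
    )
    return simulate_counts(spec)
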