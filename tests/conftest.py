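import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from omicsgsn.io_preprocess import FeatureMatrix, OmicKind
from omicsgsn.synthetic_data import SyntheticSpec, generate_multiomics


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples with hand-picked values."""
    return FeatureMatrix(
        omic_kind=OmicKind.EXPRESSION,
        gene_ids=["TP53", "PTEN", "SPOP"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array([
            [2.0, 4.0, 6.0, 8.0],
            [3.0, 3.0, 3.0, 3.0],
            [0.0, 1.0, 0.0, 1.0],
        ]),
    )


@pytest.fixture
def colinear_points():
    """10 colinear points at arc-length positions 0..9 (embedded in 2-D)."""
    t = np.arange(10, dtype=float)
    return np.column_stack([t / np.sqrt(2), t / np.sqrt(2)])


@pytest.fixture(scope="session")
def cluster_points():
    """3 well-separated Gaussian clusters: n=60, 10-dim, seeded."""
    rng = np.random.default_rng(42)
    centers = rng.normal(scale=10.0, size=(3, 10))
    pts = np.vstack([c + rng.normal(scale=1.0, size=(20, 10)) for c in centers])
    labels = np.repeat(np.arange(3), 20)
    return pts, labels


@pytest.fixture(scope="session")
def small_generated():
    """A small but fully featured synthetic dataset (fast to regenerate)."""
    spec = SyntheticSpec(n_samples=60, n_genes_raw=200, n_genes_signal=14, seed=7)
    return spec, generate_multiomics(spec)
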