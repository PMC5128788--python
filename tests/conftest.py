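import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hilltac import CommunityTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_table():
    """3 taxa x 2 samples with column sums (6, 5)."""
    return CommunityTable(
        taxon_ids=("OTU1", "OTU2", "OTU3"),
        sample_ids=("A", "B"),
        counts=np.array([[5, 0], [1, 2], [0, 3]]),
    )


@pytest.fixture
def three_sample_table():
    """Small 3-sample table for exhaustive-permutation TAC checks."""
    counts = np.array(
        [
            [4, 0, 1],
            [0, 2, 0],
            [1, 1, 0],
            [0, 0, 3],
            [2, 0, 0],
        ]
    )
    return CommunityTable(
        taxon_ids=tuple(f"OTU{i}" for i in range(1, 6)),
        sample_ids=("A", "B", "C"),
        counts=counts,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160930)


def random_abundance_vectors(n_vectors, rng, max_taxa=40, max_count=200):
    """Random non-degenerate integer abundance vectors (shared helper)."""
    out = []
    while len(out) < n_vectors:
        s = rng.integers(1, max_taxa + 1)
        v = rng.integers(0, max_count + 1, size=s)
        if v.sum() > 0:
            out.append(v)
    return out
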