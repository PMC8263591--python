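import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gyntransloc import AbundanceTable, read_tree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def balanced_tree():
    """Four-tip balanced tree, all unit branches, zero-length root edge."""
    return read_tree("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def small_counts():
    """3 taxa x 2 samples with hand-checkable column sums 12 and 13."""
    return AbundanceTable(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        np.array([[10.0, 0.0], [2.0, 8.0], [0.0, 5.0]]),
        "counts",
    )


def random_counts_table(rng, n_taxa=12, n_samples=8, depth=500):
    probs = rng.dirichlet(np.ones(n_taxa), size=n_samples)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs]).T
    # guard against an all-zero column at tiny depth
    counts[0, counts.sum(axis=0) == 0] = 1
    return AbundanceTable(
        [f"t{i}" for i in range(n_taxa)],
        [f"s{j}" for j in range(n_samples)],
        counts.astype(float),
        "counts",
    )
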