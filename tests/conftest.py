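import numpy as np
import pytest

import neuromask as nm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast cohort for plumbing tests (not for recovery claims)."""
    spec = nm.SyntheticSpec(n_subjects=24, q=12, n_blocks=3, t=80, seed=7)
    return nm.generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_config():
    return nm.RunConfig(q=12, k=4, max_epochs=5, seed=7)


def random_sparse_adjacency(q, rng, density=0.4):
    """Random symmetric nonnegative adjacency with zero diagonal."""
    a = (rng.random((q, q)) < density) * rng.random((q, q))
    a = np.triu(a, 1)
    return a + a.T
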