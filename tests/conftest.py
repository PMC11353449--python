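import numpy as np
import pytest
from hypothesis import settings

import pdmaxent as px

settings.register_profile("suite", deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_problem():
    """Seeded 6x30 synthetic instance used across solver tests."""
    ds = px.generate_synthetic(m=6, n=30, sparsity=2, l=50_000, signal_scale=2.0, seed=3)
    return ds.problem()


@pytest.fixture
def tiny_problem():
    """Hand-built 2-feature, 4-site problem with uniform prior."""
    features = px.FeatureMatrix(
        np.array([[0.0, 0.2, 0.7, 1.0], [1.0, 0.4, 0.1, 0.0]])
    )
    prior = np.full(4, 0.25)
    empirical = np.array([0.1, 0.2, 0.3, 0.4])
    return px.MaxEntProblem(features, prior, empirical)


def random_distribution(rng, n):
    p = rng.random(n)
    return p / p.sum()
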