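import numpy as np
import pytest

from cohortgcn import (
    CVScheme,
    GCNConfig,
    SyntheticSpec,
    generate,
    kernel_matrix,
    propagation_operator,
    PopulationGraph,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, low=0.0, high=1.0):
    """Random valid connectome matrix: symmetric, zero diagonal, weights in [low, high]."""
    m = rng.uniform(low, high, size=(n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def small_cohort():
    """Separable mini cohort: 40 labeled + 20 unlabeled, 8 ROIs."""
    spec = SyntheticSpec(
        n_labeled=40, n_unlabeled=20, n_rois=8, prevalence=0.4,
        effect_size=0.15, noise_sd=0.02, seed=3,
    )
    return generate(spec)


@pytest.fixture
def tiny_graph(rng):
    """7-node labeled/test/unlabeled graph for forward/backward checks."""
    X = rng.normal(size=(7, 4))
    A = kernel_matrix(X, sigma=1.0)
    S = propagation_operator(A)
    y = np.array([1, 0, 1, 0, 1, -1, 0])
    masks = {
        "train_labeled": np.array([1, 1, 1, 1, 1, 0, 0], bool),
        "test_labeled": np.array([0, 0, 0, 0, 0, 0, 1], bool),
        "unlabeled": np.array([0, 0, 0, 0, 0, 1, 0], bool),
    }
    return PopulationGraph(
        X=X, A=A, S=S, sigma=1.0, node_ids=[f"s{i}" for i in range(7)], y=y, masks=masks
    )


@pytest.fixture
def fast_gcn_config():
    return GCNConfig(n_layers=2, n_filters=8, max_epochs=150, seed=0)
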