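import numpy as np
import pytest

from pdscreen.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant cohort reused by read-only tests."""
    cfg = CohortConfig(n_participants=60, pd_fraction=0.5, seed=7)
    participants, sessions = generate_cohort(cfg)
    return cfg, participants, sessions


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_blobs(n_per_class: int, dim: int, separation: float, seed: int = 0):
    """Two Gaussian blobs along the first coordinate; returns (X, y)."""
    g = np.random.default_rng(seed)
    X0 = g.normal(0.0, 1.0, size=(n_per_class, dim))
    X1 = g.normal(0.0, 1.0, size=(n_per_class, dim))
    X1[:, 0] += separation
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class), np.ones(n_per_class)])
    order = g.permutation(2 * n_per_class)
    return X[order], y[order]
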