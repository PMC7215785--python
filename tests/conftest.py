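import numpy as np
import pytest
from hypothesis import settings

from carlogit.data_model import CrashDataset, chain_graph

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(n=60, p=2, q=2, n_segments=5, seed=0, beta=None, alpha=None, phi=None):
    """Small synthetic dataset with named covariates for unit tests."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p)])
    Z = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(q)])
    seg = rng.integers(1, n_segments + 1, size=n)
    beta = np.zeros(p + 1) if beta is None else np.asarray(beta, float)
    alpha = np.zeros(q + 1) if alpha is None else np.asarray(alpha, float)
    graph = chain_graph(n_segments)
    phi_full = np.zeros(n_segments) if phi is None else np.asarray(phi, float)
    latent = X @ beta + phi_full[seg - 1] + rng.logistic(size=n)
    mu2 = np.exp(np.clip(Z @ alpha, -30, 30))
    y = np.where(latent <= 0, 1, np.where(latent <= mu2, 2, 3))
    return CrashDataset(
        y=y,
        X=X,
        Z=Z,
        segments=seg,
        x_names=("constant",) + tuple(f"x{i}" for i in range(1, p + 1)),
        z_names=("constant",) + tuple(f"z{i}" for i in range(1, q + 1)),
        graph=graph,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
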