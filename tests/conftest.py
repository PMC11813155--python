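import numpy as np
import pytest

import txpred as tx


@pytest.fixture(scope="session")
def small_dataset():
    """Sparse-architecture panel: 80 lines x 120 genes, 6 causal."""
    cfg = tx.SimulationConfig(
        n_lines=80, n_genes=120, n_factors=4, architecture="sparse",
        n_causal=6, target_H2m=0.8, seed=101,
    )
    return tx.simulate_dataset(cfg, n_terms=12, size_range=(5, 25))


@pytest.fixture(scope="session")
def go_dataset():
    """Gene-set-enriched panel: all causal genes inside GO:CAUSAL."""
    cfg = tx.SimulationConfig(
        n_lines=100, n_genes=300, n_factors=5, architecture="go_enriched",
        n_causal=10, target_H2m=0.8, seed=202,
    )
    return tx.simulate_dataset(cfg, n_terms=20, size_range=(5, 30))


@pytest.fixture
def toy_regression():
    """Dense small regression instance with a known sparse signal."""
    rng = np.random.default_rng(11)
    n, m = 60, 25
    X = rng.normal(size=(n, m))
    beta = np.zeros(m)
    beta[:3] = [2.0, -1.5, 1.0]
    y = X @ beta + rng.normal(scale=0.5, size=n)
    return X, y, beta
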