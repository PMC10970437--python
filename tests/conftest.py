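import numpy as np
import pytest

from drgnet import (
    EffectProfile,
    EstimatorConfig,
    SyntheticConfig,
    VaryingCoefficientNetwork,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_panel():
    """Small panel with a planted sensitivity-varying DAG (shared, read-only)."""
    cfg = SyntheticConfig(n_cell_lines=150, n_genes=8, n_true_edges=10, noise_sd=0.3, seed=42)
    return cfg, *generate_dataset(cfg)


@pytest.fixture
def fast_estimator():
    """Estimator settings sized for unit tests."""
    return EstimatorConfig(n_lambda=12)


def make_network(matrix, cell_line_id, gene_ids, m=0.0):
    matrix = np.asarray(matrix, dtype=float)
    np.fill_diagonal(matrix, 0.0)
    return VaryingCoefficientNetwork(matrix, cell_line_id, m, list(gene_ids))


@pytest.fixture
def network_factory():
    return make_network
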