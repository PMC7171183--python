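import numpy as np
import pytest

from mhc_escape import simulate
from mhc_escape.core_io import CountMatrix
from mhc_escape.normalization import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded synthetic cohort small enough for every stage."""
    cfg = simulate.SimConfig(
        n_genes=300, n_pre=24, n_res=4, n_prog=12,
        n_immune_program=10, flow_n_pre=10, flow_n_prog=10, seed=42,
    )
    return cfg, simulate.simulate_cohort(cfg)


@pytest.fixture()
def random_counts():
    def _make(n_genes=50, n_samples=4, seed=0, low=0, high=200):
        rng = np.random.default_rng(seed)
        vals = rng.integers(low, high, size=(n_genes, n_samples))
        return CountMatrix(
            [f"G{i:03d}" for i in range(n_genes)],
            [f"S{j}" for j in range(n_samples)],
            vals,
        )

    return _make


@pytest.fixture()
def expr_from_array():
    def _make(values, gene_ids=None, sample_ids=None, **kw):
        values = np.asarray(values, dtype=float)
        g = gene_ids or [f"G{i}" for i in range(values.shape[0])]
        s = sample_ids or [f"S{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(g, s, values, **kw)

    return _make
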