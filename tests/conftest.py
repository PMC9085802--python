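import numpy as np
import pytest

import gclpy as g


@pytest.fixture(scope="session")
def small_grn():
    """One fixed 100-gene regulatory network, reused across tests."""
    return g.generate_grn(n_genes=100, avg_degree=3, rng=12345)


@pytest.fixture(scope="session")
def small_cohort(small_grn):
    """Homogeneous 30-cell cohort simulated from ``small_grn``."""
    return g.generate_cohort(small_grn, n_cells=30, n_inoperative=3, rng=54321)


@pytest.fixture(scope="session")
def default_scale_cohort():
    """Homogeneous cohort at the study's default scale (N=200, M=50)."""
    rng = np.random.default_rng(1)
    grn = g.generate_grn(rng=rng.spawn(1)[0])
    return g.generate_cohort(grn, rng=rng.spawn(1)[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def homogeneous_cohort(seed, n_genes=200, n_cells=60):
    """Null cohort: shared base profile with per-cell noise of varying
    amplitude (the right-skewed dissimilarity geometry of real scRNA-seq)."""
    r = np.random.default_rng(seed)
    base = r.lognormal(1.0, 1.0, size=n_genes)
    sds = r.uniform(0.2, 0.8, size=n_cells)
    vals = base[:, None] * r.lognormal(0, 1, size=(n_genes, n_cells)) ** sds[None, :]
    return g.ExpressionMatrix(vals)


def coordinated_cohort(seed, n_genes=60, n_cells=30, noise=0.05):
    """Strongly coordinated cohort: every gene tracks one latent cell state."""
    r = np.random.default_rng(seed)
    latent = r.uniform(0.5, 2.0, size=n_cells)
    gains = r.uniform(0.5, 2.0, size=n_genes)
    vals = np.outer(gains, latent) * r.lognormal(0, noise, size=(n_genes, n_cells))
    return g.ExpressionMatrix(vals)
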