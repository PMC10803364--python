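import numpy as np
import pytest

from molqtl.sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort small enough for fast end-to-end tests."""
    return SimConfig(
        seed=11,
        n_variants=400,
        n_genes=30,
        n_clusters=10,
        n_samples_per_tissue=(40, 35, 30),
        n_gwas_samples=300,
        chromosome_length=5_000_000,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
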