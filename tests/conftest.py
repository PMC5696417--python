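import numpy as np
import pytest

from deltapop.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across tests."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=60,
        loci_per_gene=8,
        n_intergenic=600,
        n_adaptive_loci=5,
        missing_rate=0.05,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
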