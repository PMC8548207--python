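import numpy as np
import pytest

from evmap.synthetic import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """One well-separated 5-type sample, no junk: shared by several suites."""
    cfg = SimConfig(n_samples=1, nuclei_per_sample=1200, n_genes=800,
                    n_de_genes=20, seed=101)
    return simulate_experiment(cfg), cfg


@pytest.fixture(scope="session")
def multisample_sim():
    """Three samples with planted DE, used by reporter and DE suites."""
    cfg = SimConfig(n_samples=3, nuclei_per_sample=500, n_genes=600,
                    n_de_genes=30, seed=202)
    return simulate_experiment(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(7)
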