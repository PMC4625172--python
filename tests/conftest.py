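import numpy as np
import pytest

from admixvar import AdmixtureSimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A modest admixed panel shared by read-only tests: 300 individuals,
    6 chromosomes x 40 loci."""
    cfg = AdmixtureSimConfig(
        n_individuals=300, n_chromosomes=6, loci_per_chromosome=40, seed=101
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """Panel at the generator's default admixture moments (mean 0.80, SD 0.11)."""
    cfg = AdmixtureSimConfig(n_individuals=500, seed=202)
    return simulate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
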