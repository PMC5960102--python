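import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hymevol.phylo import default_phylogeny, null_phylogeny
from hymevol.simulate import SimulationConfig, simulate_methylome


@pytest.fixture(scope="session")
def phylo():
    return default_phylogeny()


@pytest.fixture(scope="session")
def null_phylo():
    return null_phylogeny()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_orthologs=60)


@pytest.fixture(scope="session")
def methylome_data():
    """One shared bimodal synthetic methylome at the default study conditions."""
    return simulate_methylome(SimulationConfig(seed=21, n_genes=200))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
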