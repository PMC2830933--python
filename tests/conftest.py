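import numpy as np
import pytest

from calvingsem.gibbs import MCMCConfig, run_chains
from calvingsem.simulate import SimulationDesign, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """600 records under RMM3 truth; shared by the slower integration tests."""
    design = SimulationDesign(n_records=600, n_sires=25, n_mgs=50,
                              n_herd_years=15, seed=42)
    records, latent, truth = simulate_dataset(design, variant="RMM3")
    return records, latent, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short RMM3 fit of the shared dataset (250 retained draws)."""
    records, _, _ = small_dataset
    config = MCMCConfig(n_chains=1, n_iterations=600, burn_in=100, thin=2,
                        seed=314)
    return run_chains(records, "RMM3", config=config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
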