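import numpy as np
import pandas as pd
import pytest

from compadapt.hiervar import HierParams
from compadapt.synth import SimConfig, simulate_fitness_gains, simulate_founder_panel


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """2 modules x 2 genes x 2 populations x 2 replicates (16 measurements)."""
    return SimConfig(
        n_modules=2, genes_per_module=2, n_populations_per_founder=2,
        n_replicate_measurements=2, seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_config) -> pd.DataFrame:
    return simulate_founder_panel(small_config)


@pytest.fixture(scope="session")
def small_data(small_config, small_panel) -> pd.DataFrame:
    params = HierParams(alpha=2.0, beta=-0.4, sigma_m=1.3, sigma_g=0.7,
                        sigma_p=1.1, sigma_tau=0.9)
    return simulate_fitness_gains(small_panel, params, small_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
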