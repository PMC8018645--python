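import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metaplast.simulate import CompoundSpec, SimSpec, simulate_panel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_panel():
    """5 varieties x 3 locations x 2 blocks x 6 compounds with mild G x E."""
    comps = [
        CompoundSpec(f"c{i}", mu=10 + i, sigma_g=1.0, sigma_e=1.5, sigma_gxe=0.4, sigma_resid=0.3)
        for i in range(6)
    ]
    spec = SimSpec(
        n_varieties=5, n_locations=3, n_years=1, n_blocks=2,
        compounds=comps, block_sd=0.1, seed=42,
    )
    table, truth = simulate_panel(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def noiseless_panel():
    """Zero-residual panel: block means equal the generating cell model."""
    comps = [
        CompoundSpec(f"c{i}", mu=5.0, sigma_g=1.0, sigma_e=2.0, sigma_gxe=0.5, sigma_resid=0.0)
        for i in range(3)
    ]
    spec = SimSpec(
        n_varieties=4, n_locations=5, n_years=2, n_blocks=2, compounds=comps, seed=11
    )
    table, truth = simulate_panel(spec)
    return spec, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_means(rng):
    """A complete 6 x 8 variety x environment means matrix."""
    return pd.DataFrame(
        rng.normal(20.0, 3.0, (6, 8)),
        index=[f"V{i}" for i in range(6)],
        columns=[f"E{j}" for j in range(8)],
    )
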