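import numpy as np
import pytest

import apcburden as ab


@pytest.fixture(scope="session")
def small_grid():
    """4 age groups x 8 years with moderate counts (72-220 events per cell)."""
    truth = ab.generate_apc_truth(A=4, T=8, scenario="full_apc", seed=42)
    pop = ab.generate_population(A=4, T=8, base_size=5e5)
    grid, _ = ab.generate_dataset(truth, pop, seed=42)
    return truth, pop, grid


@pytest.fixture(scope="session")
def small_fit(small_grid):
    _, _, grid = small_grid
    return ab.fit_apc(grid, ab.APCModelSpec(seed=7))


@pytest.fixture(scope="session")
def study_population():
    """Default desk-scale population: 18 five-year groups x 32 years."""
    return ab.generate_population()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
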