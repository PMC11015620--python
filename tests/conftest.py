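import numpy as np
import pytest

from landgen.synthdata import SimulationConfig, simulate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Compact scenario reused across unit tests: 12 populations x 6
    individuals, 200 neutral + 20 clinal loci on a 20x20 landscape."""
    cfg = SimulationConfig(
        grid_rows=20, grid_cols=20, n_pops=12, n_ind_per_pop=6,
        n_neutral=200, n_adaptive=20, beta=1.5, seed=42,
    )
    return cfg, *simulate_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
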