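import numpy as np
import pytest

from spermsel import SimulationConfig, run_grid
from spermsel.experiment import PAPER_PARTNER_LEVELS, PAPER_SIGMA_F_LEVELS


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config():
    """A cheap but non-trivial condition: 40 pairs, 3 partners."""
    return SimulationConfig(
        sigma_F=1.5, n_partners=3, n_females=40, n_males=40, eggs_per_female=5, seed=11
    )


@pytest.fixture(scope="session")
def reduced_paper_grid():
    """The published factorial design at 250 replicates per cell.

    Shared across tests that read off effect sizes and quantile patterns;
    250 replicates keep the whole suite fast while leaving the eta-squared
    estimates stable (they estimate a ratio of variance components that
    does not depend on the replicate count).
    """
    base = SimulationConfig(sigma_F=1.0, n_partners=2)
    return run_grid(
        base, PAPER_SIGMA_F_LEVELS, PAPER_PARTNER_LEVELS, 250, master_seed=94
    )
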