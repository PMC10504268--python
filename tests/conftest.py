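import numpy as np
import pytest

from minsize.mindyn import Grid1D, MinModelParams, simulate
from minsize.synthdata import LineageConfig


@pytest.fixture(scope="session")
def wt_params():
    return MinModelParams()


@pytest.fixture(scope="session")
def wt_sim_600s(wt_params):
    """One full wild-type run: L = 4 um, dx = 0.05 um, 600 s.

    Shared across the oscillation, conservation and profile tests to keep
    the suite fast.
    """
    grid = Grid1D.for_length(4.0, dx=0.05)
    return simulate(wt_params, grid, t_end=600.0, sample_dt=1.0, seed=0,
                    perturbation=0.01)


@pytest.fixture()
def noiseless_config():
    """Lineage generator with every noise source off and no induction."""
    return LineageConfig(n_lineages=3, n_generations=8, seed=42)


@pytest.fixture()
def induction_config():
    """Noiseless lineages with minE induction switched on at generation 5."""
    return LineageConfig(n_lineages=4, n_generations=18,
                         induction_start_gen=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
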