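import numpy as np
import pytest

from cycleflux import SimulationGrid, steady_state_init
from cycleflux import library


@pytest.fixture(scope="session")
def bxpc3():
    return library.load_cell_line("BxPC-3")


@pytest.fixture(scope="session")
def grid():
    return SimulationGrid(dt=0.5, age_bin=0.5, horizon=96.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Cheap grid for fitting-heavy tests."""
    return SimulationGrid(dt=1.0, age_bin=1.0, horizon=96.0)


@pytest.fixture(scope="session")
def init_state(bxpc3, grid):
    return steady_state_init(bxpc3, 1000.0, grid)


@pytest.fixture(scope="session")
def gem20():
    return library.load_drug_model("bxpc3_gemcitabine_20nM")


@pytest.fixture(scope="session")
def erl1():
    return library.load_drug_model("bxpc3_erlotinib_1uM")


@pytest.fixture(scope="session")
def gem_schedule():
    return library.single_drug_schedule("gemcitabine", 0.0, 6.0)


@pytest.fixture(scope="session")
def erl_schedule():
    return library.single_drug_schedule("erlotinib", 0.0, 48.0)
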