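import numpy as np
import pytest

from protonrange import (
    NUCLIDES,
    FrameSchedule,
    StoppingModel,
    build_irf_basis,
    load_cross_section,
    make_beta_grid,
)
from importlib import resources


@pytest.fixture(scope="session")
def bk_model():
    return StoppingModel.bragg_kleeman()


@pytest.fixture(scope="session")
def table_model():
    path = resources.files("protonrange.data") / "stopping_power_water_synthetic.csv"
    return StoppingModel.from_csv(path)


@pytest.fixture(scope="session")
def beta_grid():
    return make_beta_grid()


@pytest.fixture(scope="session")
def schedule75():
    return FrameSchedule.uniform(75, 60.0)


@pytest.fixture(scope="session")
def basis75(schedule75, beta_grid):
    return build_irf_basis(schedule75, beta_grid)


@pytest.fixture(scope="session")
def xs_all():
    return {name: load_cross_section(name) for name in NUCLIDES}


@pytest.fixture(scope="session")
def three_component_tac(schedule75):
    """Noiseless equal-initial-activity mixture of the three nuclides."""
    tac = np.zeros(len(schedule75))
    for spec in NUCLIDES.values():
        lam = spec.decay_constant_s
        tac += (np.exp(-lam * schedule75.start_s)
                - np.exp(-lam * schedule75.end_s)) / lam
    return tac
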