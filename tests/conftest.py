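import numpy as np
import pytest

from fflscope.config import RunConfig
from fflscope.synthetic import SimulationDesign, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort shared by the heavier recovery tests."""
    return generate_cohort(SimulationDesign(), seed=1)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down design for fast unit tests of the generator contract."""
    return SimulationDesign(
        subtype_counts={"ATC": 6, "MTC": 20, "PTC": 20, "FTA": 8, "normal": 25},
        n_genes=400,
        n_mirnas=60,
        n_planted_up=30,
        n_planted_down=8,
        n_shared_de=10,
        n_per_subtype_de=10,
        n_til_sets=5,
        n_other_down_mirnas=5,
        n_up_mirnas=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
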