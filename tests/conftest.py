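import numpy as np
import pytest

from ssisfit import BindingParameters, NoiseSpec, get_design, simulate_heats


@pytest.fixture(scope="session")
def mg_design():
    """The magnesium titration at 16.5 mM ionic strength (reference truth)."""
    return get_design("mg-16.5")


@pytest.fixture(scope="session")
def mg_schedule(mg_design):
    return mg_design.schedule()


@pytest.fixture(scope="session")
def mg_params(mg_design) -> BindingParameters:
    return mg_design.params


@pytest.fixture(scope="session")
def noiseless_heats(mg_params, mg_schedule):
    return simulate_heats(mg_params, mg_schedule, NoiseSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
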