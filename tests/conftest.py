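import numpy as np
import pytest

from thermguts import GAMMARUS_PULEX_PARAMS, TemperatureScenario
from thermguts.synthetic_data import default_henry_design, generate


@pytest.fixture(scope="session")
def ref_params():
    """Reference G. pulex calibration (T_c = 11 degC)."""
    return GAMMARUS_PULEX_PARAMS


@pytest.fixture(scope="session")
def ref_params_no_background(ref_params):
    """Reference parameters with the background hazard switched off."""
    return ref_params.with_(h_b=0.0)


@pytest.fixture(scope="session")
def henry_design():
    return default_henry_design()


@pytest.fixture(scope="session")
def henry_observations(henry_design, ref_params):
    """One synthetic realization of the reference assay."""
    return generate(henry_design, ref_params, seed=20260923)


@pytest.fixture
def constant_scenario():
    def make(temp_celsius, t_end=8.0):
        return TemperatureScenario(kind="constant", base_mean=temp_celsius,
                                   t_end=t_end)
    return make


@pytest.fixture
def fig3_heatwave():
    """Daily 12 +/- 4 degC fluctuation with a 4 degC, 10-day heatwave at day 10."""
    return TemperatureScenario(kind="heatwave", base_mean=12.0, amplitude=4.0,
                               hw_start=10.0, hw_duration=10.0,
                               hw_intensity=4.0, t_end=200.0)
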