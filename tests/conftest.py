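import numpy as np
import pytest

from micromi import (SimulationConfig, default_life_table, default_schedule,
                     sample_initial_population)
from micromi.params import ParameterVector


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def small_population():
    return sample_initial_population(2000, seed=11)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_params():
    return ParameterVector()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def zero_trend_params(**overrides) -> ParameterVector:
    """Parameters with every secular trend switched off."""
    base = dict(trend_bmi_rate=0.0, trend_sbp_slope=0.0, trend_tchol_slope=0.0,
                trend_smoking_quit=0.0, trend_diabetes_inc=0.0, cf_trend=0.0)
    base.update(overrides)
    return ParameterVector(**base)
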