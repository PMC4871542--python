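import numpy as np
import pytest

from htnscreen import Scenario, synth_parameter_set


@pytest.fixture(scope="session")
def params():
    """Synthetic base-case parameter set (published point estimates plus
    synthetic life table and prevalence)."""
    return synth_parameter_set()


@pytest.fixture
def scenario_m55():
    return Scenario(sex="male", start_age=55, horizon="ten_year", strategy="one_off")


@pytest.fixture
def comparator_m55():
    return Scenario(sex="male", start_age=55, horizon="ten_year", strategy="none")


def make_scenario(sex="male", start_age=55, horizon="ten_year",
                  strategy="none", **kw):
    return Scenario(sex=sex, start_age=start_age, horizon=horizon,
                    strategy=strategy, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
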