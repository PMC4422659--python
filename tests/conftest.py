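import numpy as np
import pytest

from scallopiam.defaults import (BGC_DEFAULTS, BGC_INITIAL, ECON_INITIAL,
                                 SCALLOP_DEFAULTS, initial_population_state)


@pytest.fixture(scope="session")
def gb():
    return SCALLOP_DEFAULTS["GB"]


@pytest.fixture(scope="session")
def ma():
    return SCALLOP_DEFAULTS["MA"]


@pytest.fixture(scope="session")
def gb_bgc():
    return BGC_DEFAULTS["GB"]


@pytest.fixture(scope="session")
def ma_bgc():
    return BGC_DEFAULTS["MA"]


@pytest.fixture(scope="session")
def econ_init():
    return ECON_INITIAL


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def init_states():
    return {r: initial_population_state(r) for r in ("GB", "MA")}


@pytest.fixture(scope="session")
def hindcast_df():
    """One shared forced hindcast run (2000-2012), synthetic forcing, seed 1."""
    from scallopiam.simulator import ScenarioConfig, run_hindcast

    cfg = ScenarioConfig(scenario="constant2008", end_year=2013, seed=1)
    return run_hindcast(cfg).runs[0]
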