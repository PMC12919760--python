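import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from her2ce.datasets import (TrialSimSpec, make_base_case_bundle,
                             simulate_trial_ipd, synthetic_life_table)
from her2ce.model import DecisionModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 11


@pytest.fixture(scope="session")
def sim_spec():
    return TrialSimSpec()


@pytest.fixture(scope="session")
def ipd(sim_spec):
    return simulate_trial_ipd(sim_spec, SEED)


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def bundle(ipd, sim_spec, life_table):
    return make_base_case_bundle(ipd=ipd, sim_spec=sim_spec,
                                 life_table=life_table, seed=SEED)


@pytest.fixture(scope="session")
def base_results(bundle, life_table):
    return DecisionModel(bundle, life_table).run()


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
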