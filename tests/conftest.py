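import pytest

from ogclinic.config import default_config
from ogclinic.scenarios import SCENARIO_IDS, make_scenario, run_experiment


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def battery_small(config):
    """Base case + all scenarios at reduced scale (8 reps x 2 days), one seed.

    Shared across the directional-property and invariance tests; the gaps they
    assert are tens of percent and stable at this scale.
    """
    return {
        sid: run_experiment(config, make_scenario(sid), n_replications=8, days=2, master_seed=5)
        for sid in SCENARIO_IDS
    }


@pytest.fixture(scope="session")
def base_full(config):
    """The validation-scale base case: 30 replications x 5 days."""
    return run_experiment(config, make_scenario("base"), n_replications=30, days=5, master_seed=1)
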