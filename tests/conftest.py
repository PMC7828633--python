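import warnings

import pytest
from hypothesis import HealthCheck, settings

import cns_whatif as cw

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    """The eight fully characterized reference drugs, keyed by name."""
    return {d.name: d for d in cw.reference_drug_panel()}


@pytest.fixture(scope="session")
def physiology():
    return cw.default_physiology()


@pytest.fixture(scope="session")
def scenario_grid(panel):
    """Full reference-panel x scenario grid (computed once per session)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cw.run_grid(list(panel.values()), cw.pathophysiological_scenarios())


@pytest.fixture(scope="session")
def caffeine_result(panel):
    return cw.simulate_drug(panel["caffeine"])


@pytest.fixture(scope="session")
def morphine_result(panel):
    return cw.simulate_drug(panel["morphine"])
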