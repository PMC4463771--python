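import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from milklip.identify import MatchSettings, identify_all
from milklip.simulate import (
    DEFAULT_SPIKE_SHEET,
    NoiseModel,
    make_fixture,
    simulate_msmsall,
)


@pytest.fixture(scope="session")
def match_settings():
    return MatchSettings()


@pytest.fixture(scope="session")
def lacprodan_clean():
    """Zero-noise Lacprodan-like simulation with its identifications."""
    comp = make_fixture("lacprodan")
    experiment, sidecar = simulate_msmsall(comp, DEFAULT_SPIKE_SHEET, NoiseModel())
    idents = identify_all(experiment)
    return comp, experiment, idents


@pytest.fixture(scope="session")
def human1_clean():
    comp = make_fixture("human1")
    experiment, sidecar = simulate_msmsall(comp, DEFAULT_SPIKE_SHEET, NoiseModel())
    idents = identify_all(experiment)
    return comp, experiment, idents
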