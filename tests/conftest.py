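import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from spliceoscope.simulate import SimulationConfig, simulate_cohort, simulate_reference


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=1, n_null_events=12)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_study(small_reference):
    """(junction table, gene counts, sample sheet, truth) of the default
    mutation-stratified cohort."""
    return simulate_cohort(small_reference)


@pytest.fixture(scope="session")
def small_events(small_reference, small_study):
    from spliceoscope.events import enumerate_events

    table = small_study[0]
    return enumerate_events(small_reference.models, table)


@pytest.fixture(scope="session")
def small_psi(small_events, small_study):
    from spliceoscope.events import compute_psi

    return compute_psi(small_events, small_study[0])
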