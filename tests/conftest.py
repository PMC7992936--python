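import pytest
from hypothesis import HealthCheck, settings

from powergap import SimConfig, audit_registry, generate_registry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_registry():
    """The default study conditions: 264 synthetic trials, fixed seed."""
    records, truths = generate_registry(SimConfig())
    return records, truths


@pytest.fixture(scope="session")
def default_audit(default_registry):
    records, _ = default_registry
    return audit_registry(records)


@pytest.fixture(scope="session")
def large_registry():
    """Bigger registry for tally oracles and fraction-recovery checks."""
    config = SimConfig(n_trials=2000, seed=7)
    records, truths = generate_registry(config)
    return records, truths
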