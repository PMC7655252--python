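import pytest
from hypothesis import HealthCheck, settings

from emrqc.registry import default_rule_config, fixture_codeset_registry
from emrqc.synthetic import generate_record

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return default_rule_config()


@pytest.fixture(scope="session")
def registry():
    return fixture_codeset_registry()


@pytest.fixture()
def perfect_record(config, registry):
    """A record satisfying every mandatory and coding rule."""
    import random

    record, expected = generate_record(
        5, config=config, registry=registry, rng=random.Random(1)
    )
    assert expected.missing_count == 0 and expected.noncompliant_count == 0
    return record
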