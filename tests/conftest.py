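import pytest

from oralcea import (
    CostLedger,
    TreatmentPolicy,
    load_default_config,
    table_counts,
)


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def registry(config):
    return config.registry


@pytest.fixture(scope="session")
def values(registry):
    return registry.values_dict()


@pytest.fixture(scope="session")
def counts():
    return table_counts()


@pytest.fixture(scope="session")
def histology_policy(config):
    return config.histology_policy


@pytest.fixture(scope="session")
def risk_policy(config):
    return config.risk_policy


@pytest.fixture(scope="session")
def ledger(values, config):
    return CostLedger.from_values(values, **config.ledger_options)


@pytest.fixture(scope="session")
def bare_histology_policy():
    """Actions only, no visit schedules (costs irrelevant)."""
    return TreatmentPolicy(
        actions={"Severe": "excision", "Moderate": "excision", "Mild": "surveillance"}
    )


@pytest.fixture(scope="session")
def bare_risk_policy():
    return TreatmentPolicy(
        actions={"High": "excision", "Medium": "excision", "Low": "surveillance"}
    )
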