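import pytest

from gapscore import (
    Condition,
    MetricDefinition,
    MetricObservation,
    MetricTable,
    RunConfig,
    SyntheticSpec,
    generate,
)


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def toy_table():
    """Two conditions, one metric per domain, single reference years."""
    conditions = [
        Condition("dm", "Diabetes mellitus"),
        Condition("oa", "Osteoarthritis"),
    ]
    definitions = [
        MetricDefinition("mortality", "burden", units="per 100000"),
        MetricDefinition("total_spending", "cost", units="billion USD"),
        MetricDefinition("patents_granted", "innovation", units="count"),
    ]
    observations = [
        MetricObservation("dm", "mortality", 2019, 25.0),
        MetricObservation("oa", "mortality", 2019, 5.0),
        MetricObservation("dm", "total_spending", 2016, 171.5),
        MetricObservation("oa", "total_spending", 2016, 90.0),
        MetricObservation("dm", "patents_granted", 2019, 5000.0),
        MetricObservation("oa", "patents_granted", 2019, 1200.0),
    ]
    return MetricTable.from_observations(observations, conditions, definitions)


@pytest.fixture(scope="session")
def synthetic_table():
    return generate(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def planted_table():
    return generate(SyntheticSpec(planted_gap="c05", planted_paradox="c02", seed=42))
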