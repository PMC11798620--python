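import pytest

from triagesim import (
    ScenarioConfig,
    build_matrix,
    load_fixture_cohort,
    load_protocol,
    list_protocols,
)

#: Reference allocation outcomes for the nine-patient scenario at capacity 3
#: (patients 1-8; patient 9's outcomes are unreported in the reference table
#: and excluded from golden comparisons).  Columns: MD PA FL NY CA NE.
REFERENCE_GRID: dict[int, tuple[str, ...]] = {
    1: ("O", "O", "O", "O", "***", "O"),
    2: ("O", "O", "O", "O", "O", "O"),
    3: ("***", "O", "O", "O", "***", "O"),
    4: ("O", "***", "***", "**", "O", "*"),
    5: ("**", "***", "***", "***", "O", "*"),
    6: ("***", "O", "O", "O", "O", "*"),
    7: ("***", "***", "***", "***", "***", "*"),
    8: ("O", "O", "O", "***", "O", "*"),
}

PROTOCOL_IDS = ("MD", "PA", "FL", "NY", "CA", "NE")


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def rulesets():
    return [load_protocol(p) for p in list_protocols()]


@pytest.fixture(scope="session")
def rulesets_by_id(rulesets):
    return {r.id: r for r in rulesets}


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig(n_ventilators=3, rng_seed=0)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_cohort, rulesets, scenario):
    return build_matrix(fixture_cohort, rulesets, scenario)
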