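import pytest

from oncobudget import (
    GeneratorConfig,
    fixture_assessments,
    fixture_context,
    generate_catalog,
    tables_fixture,
)


@pytest.fixture(scope="session")
def ctx():
    """2021 Sri Lanka economic context (GDP 3,815 USD, 200 LKR/USD, LE 77)."""
    return fixture_context()


@pytest.fixture(scope="session")
def fixture_rows():
    return tables_fixture()


@pytest.fixture(scope="session")
def assessments(fixture_rows, ctx):
    return fixture_assessments(fixture_rows, ctx)


@pytest.fixture()
def small_catalog():
    cfg = GeneratorConfig(seed=11, n_indications=8, n_option_groups_with_alternatives=2)
    return generate_catalog(cfg)
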