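import pytest

from pmcindex import (
    default_schema,
    gen_table4_consistent_matrix,
    load_fixture,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5")


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def coded_matrix(schema):
    """Binary matrix consistent with the published main-score table (P1-P12)."""
    return gen_table4_consistent_matrix(schema)
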