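import pytest

from hbfin import bundled_condition_table, bundled_net, table2_fixture


@pytest.fixture(scope="session")
def table():
    return bundled_condition_table()


@pytest.fixture()
def net():
    # rebuilt per test: quantification mutates node parameters
    return bundled_net()


@pytest.fixture(scope="session")
def worked_record():
    return table2_fixture()
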