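import pytest

from tremorcma import calibrated_fixture, reference_scenario


@pytest.fixture(scope="session")
def fixture():
    return calibrated_fixture()


@pytest.fixture(scope="session")
def ffs_scenario(fixture):
    return reference_scenario("ffs", fixture=fixture)


@pytest.fixture(scope="session")
def dpc_scenario(fixture):
    return reference_scenario("dpc", fixture=fixture)


@pytest.fixture(scope="session")
def ffs_labour_2018(fixture):
    return reference_scenario("ffs", labour_year=2018, fixture=fixture)


@pytest.fixture(scope="session")
def ffs_labour_2016(fixture):
    return reference_scenario("ffs", labour_year=2016, fixture=fixture)


@pytest.fixture(scope="session")
def dpc_labour_2018(fixture):
    return reference_scenario("dpc", labour_year=2018, fixture=fixture)
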