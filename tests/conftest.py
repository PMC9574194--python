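import pytest

from rsspa import load_fixture


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
def table7():
    return load_fixture("table7")


@pytest.fixture(scope="session")
def table8():
    return load_fixture("table8")


@pytest.fixture(scope="session")
def hebei_aqi(table4):
    """The eight annual composite AQI values, 2013-2020."""
    return tuple(float(v) for v in table4["AQI"])


@pytest.fixture(scope="session")
def pollutant_columns():
    return ("PM2.5", "PM10", "O3", "NO2", "CO", "SO2")
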