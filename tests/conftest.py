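import pytest

from etobench import (
    UDHAGAMANDALAM_SITE,
    Conventions,
    table1_fixture,
    table3_fixture,
)


@pytest.fixture(scope="session")
def site():
    return UDHAGAMANDALAM_SITE


@pytest.fixture(scope="session")
def conv():
    return Conventions()


@pytest.fixture(scope="session")
def climate():
    """The packaged 12-month climate normals of the study station."""
    return table1_fixture()


@pytest.fixture(scope="session")
def eto_rows():
    """Published monthly ET0 series keyed by model id (baselines included)."""
    return {s.model_id: s for s in table3_fixture()}


@pytest.fixture(scope="session")
def january(climate):
    return climate[0]
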