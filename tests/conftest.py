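import pytest

from cotnet import (AnalysisOptions, enumerate_organizations,
                    markevich_fixture, tyson_fixture)


@pytest.fixture(scope="session")
def tyson():
    return tyson_fixture()


@pytest.fixture(scope="session")
def tyson_orgs(tyson):
    return enumerate_organizations(tyson)


@pytest.fixture(scope="session")
def markevich():
    return markevich_fixture()


@pytest.fixture(scope="session")
def markevich_orgs(markevich):
    return enumerate_organizations(markevich, AnalysisOptions(timeout=300.0))
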