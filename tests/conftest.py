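import pytest

from stql import Session
from stql.fixtures import make_fixture_catalog, make_fixture_tracks


@pytest.fixture()
def tracks():
    return make_fixture_tracks()


@pytest.fixture()
def catalog():
    return make_fixture_catalog()


@pytest.fixture()
def session(catalog):
    return Session(catalog, chrom_sizes={"chr1": 100_000, "chr2": 80_000,
                                         "chr3": 60_000})
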