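import pytest

from magtrace import fixtures


@pytest.fixture(scope="session")
def bundle():
    return fixtures.load_bundle()


@pytest.fixture(scope="session")
def phototrophy_set():
    return fixtures.PHOTOTROPHY_SET


@pytest.fixture(scope="session")
def bch_set():
    return fixtures.BCH_SET
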