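import pytest

from vitalglove import load_fixture


@pytest.fixture(scope="session")
def raw_resting():
    return load_fixture("raw_resting")


@pytest.fixture(scope="session")
def raw_walking():
    return load_fixture("raw_walking")


@pytest.fixture(scope="session")
def raw_running():
    return load_fixture("raw_running")
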