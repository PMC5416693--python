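import pytest

from nscnet.synthetic import SyntheticConfig, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged per-gene MD annotation table (68 network proteins)."""
    return load_table1_fixture()


@pytest.fixture
def config():
    return SyntheticConfig(seed=7)
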