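import pytest

from statediagrams import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The bundled reference tables, loaded once per session."""
    return load_fixtures()


@pytest.fixture(scope="session")
def design(fixtures):
    return fixtures.table1


@pytest.fixture(scope="session")
def param_table(fixtures):
    return fixtures.table2


@pytest.fixture(scope="session")
def models(fixtures):
    return fixtures.table3
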