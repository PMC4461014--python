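import pytest
from hypothesis import settings

from pathconflict import ContextLexicon, PairWhitelist, StemTable, SubtypeTable

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stem_table():
    return StemTable.default()


@pytest.fixture(scope="session")
def subtype_table():
    return SubtypeTable.default()


@pytest.fixture(scope="session")
def whitelist():
    return PairWhitelist.default()


@pytest.fixture(scope="session")
def lexicon():
    return ContextLexicon.synthetic_fixture()
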