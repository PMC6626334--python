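import pytest

from adgrl4evo import fixtures
from adgrl4evo.alignment import ScoringScheme
from adgrl4evo.conservation import PropertyTable


@pytest.fixture(scope="session")
def blosum():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def cheap_scheme():
    """Small gap penalties so short test sequences still open gaps."""
    return ScoringScheme.blosum62(gap_open=4.0, gap_extend=1.0)


@pytest.fixture(scope="session")
def properties():
    return PropertyTable.default()


@pytest.fixture(scope="session")
def timetree():
    return fixtures.vertebrate_timetree()
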