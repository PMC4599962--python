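import pytest

from surnamebias import Repertoire


@pytest.fixture
def historical():
    """A small founding list: two documented surnames."""
    return Repertoire("Borgo", 1700, "marriage", {"ROSSI": 2, "BIANCHI": 1})


@pytest.fixture
def present():
    """Present-day list sharing ROSSI with the founding one."""
    return Repertoire("Borgo", 1993, "phonebook", {"ROSSI": 3, "VERDI": 1})
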