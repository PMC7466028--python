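import pytest

from oligopep import massbook


@pytest.fixture(scope="session")
def ssa():
    return massbook.ssdna_a()


@pytest.fixture(scope="session")
def ssb():
    return massbook.ssdna_b()


@pytest.fixture(scope="session")
def pep():
    return massbook.gcn4_peptide()
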