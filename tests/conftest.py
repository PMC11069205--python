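import pytest

from aluscan import synthetic


@pytest.fixture(scope="session")
def eys():
    return synthetic.eys_fixture()


@pytest.fixture(scope="session")
def insertion_pair(eys):
    return synthetic.build_alleles(eys.insertion_locus, eys.insertion)


@pytest.fixture(scope="session")
def deletion_pair(eys):
    return synthetic.build_alleles(eys.deletion_locus, eys.deletion)


@pytest.fixture(scope="session")
def consensus_library():
    return synthetic.load_consensus_library()
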