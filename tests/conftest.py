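import pytest

from carefuse.extraction import load_pattern_pack
from carefuse.vocabulary import load_packaged_ontology


@pytest.fixture(scope="session")
def registry():
    return load_packaged_ontology()


@pytest.fixture(scope="session")
def pack_no():
    return load_pattern_pack(language="no")


@pytest.fixture(scope="session")
def pack_en():
    return load_pattern_pack(language="en")
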