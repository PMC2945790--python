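from pathlib import Path

import pytest

from gvftools import generate_document, load_bundled, parse

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def ontology():
    return load_bundled()


@pytest.fixture(scope="session")
def trio_doc():
    """The committed three-record example (SNV, deletion, duplication)."""
    return parse(DATA / "example_trio.gvf")


@pytest.fixture()
def valid_doc():
    return generate_document(seed=7, n_records=40)
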