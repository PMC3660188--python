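"""Shared fixtures: bundled panels and tiny synthetic records."""

import pytest

from dyz1kit import digest, sts
from dyz1kit.core_io import SequenceRecord


@pytest.fixture(scope="session")
def enzyme_panel():
    """Bundled virtual-digest panel, keyed by enzyme name."""
    return {e.name: e for e in digest.load_enzyme_panel()}


@pytest.fixture(scope="session")
def rflp_enzymes():
    """Bundled PCR-RFLP enzyme set (all with cut offsets)."""
    path = digest.default_panel_path().with_name("rflp_enzymes.tsv")
    return {e.name: e for e in digest.load_enzyme_panel(path)}


@pytest.fixture(scope="session")
def sts_panel():
    return sts.load_sts_panel()


@pytest.fixture(scope="session")
def signatures():
    return sts.load_signatures()


@pytest.fixture
def record():
    def make(residues, rec_id="test"):
        return SequenceRecord(id=rec_id, residues=residues)

    return make
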