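import textwrap

import pytest

from pstrtool.seqio import ProteinRecord


@pytest.fixture
def write_fasta_text(tmp_path):
    """Write literal FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text))
        return path

    return _write


@pytest.fixture
def pq_family():
    """Three homologs where the first carries one extra 'PQ' unit."""
    return [
        ProteinRecord("a", "MKVCWDEPQPQPQHLSTRNAEY"),
        ProteinRecord("b", "MKVCWDEPQPQHLSTRNAEY"),
        ProteinRecord("c", "MKVCWDEPQPQHLSTRNAEY"),
    ]
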