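"""FASTA input/output and sequence validation.

Protein sequences are represented as :class:`ProteinRecord` objects: an
identifier (the FASTA header token up to the first whitespace), the
uppercased amino-acid sequence, and the full header as description.
Sequences containing the ambiguity character 'X' are excluded from every
downstream analysis; :func:`filter_x_sequences` applies that rule and
reports what it dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid sequence content."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    Attributes
    ----------
    id : str
        Header token up to the first whitespace; unique within a dataset.
    sequence : str
        Uppercase amino-acid letters; length >= 1.
    description : str
        Full FASTA header line (without the leading ``>``).
    """

    id: str
    sequence: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("empty record id")
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        if bad:
            raise FastaError(
                f"record {self.id!r}: non-alphabetic characters in sequence: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_x(self) -> bool:
        return "X" in self.sequence


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved, sequences are uppercased, ids are the header token
    up to the first whitespace.  Duplicate ids, empty files, sequence data
    before the first header, and ``*``/``-`` characters are rejected.
    """
    path = Path(path)
    text = path.read_text()
    _prescan(text, path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq or "-" in seq:
            raise FastaError(
                f"{path}: record {rec.id!r} contains '*' or '-' characters; "
                "provide ungapped protein sequences"
            )
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def _prescan(text: str, path: Path) -> None:
    """Cheap line-level syntax check so errors carry a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        return
    raise FastaError(f"{path}: empty file")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=_extra_description(r))
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


def _extra_description(record: ProteinRecord) -> str:
    desc = record.description
    if desc.startswith(record.id):
        desc = desc[len(record.id):].strip()
    return desc


def filter_x_sequences(
    records: list[ProteinRecord],
) -> tuple[list[ProteinRecord], list[str]]:
    """Drop sequences containing 'X' residues.

    Returns ``(kept, dropped_ids)`` with input order preserved in both.
    The dropped ids are also reported on the package logger, since the
    exclusion silently changes every downstream count.
    """
    kept = [r for r in records if not r.has_x]
    dropped = [r.id for r in records if r.has_x]
    if dropped:
        logger.info(
            "excluded %d sequence(s) containing 'X' residues: %s",
            len(dropped),
            ", ".join(dropped),
        )
    return kept, dropped
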