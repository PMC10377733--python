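"""Best-homolog selection from sequence-search tabular output.

The standalone single-protein mode starts from one query protein and a
sequence search (e.g. BLASTP) against a collection of proteomes; from
the tabular hits it keeps one protein per proteome -- the highest
bitscore, ties broken by lowest e-value and then lexicographic subject
id -- before handing the selected homologs to the repeat pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import math

import pandas as pd

#: BLAST ``-outfmt 6`` default columns.
OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

#: Default proteome tag: token after the last '_' of the subject id,
#: matching UniProt-style ids such as ``sp|P12345|GENE_HUMAN``.
DEFAULT_TAG_PATTERN = r"_([^_|]+)$"


@dataclass(frozen=True)
class SearchHit:
    """One tabular search hit with its proteome assignment."""

    query_id: str
    subject_id: str
    proteome_tag: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.subject_id!r}")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"non-finite bitscore for {self.subject_id!r}")


def extract_proteome_tag(
    subject_id: str,
    pattern: str = DEFAULT_TAG_PATTERN,
    mapping: Mapping[str, str] | None = None,
) -> str:
    """Proteome tag for a subject id, via mapping file or regex group 1."""
    if mapping is not None and subject_id in mapping:
        return mapping[subject_id]
    m = re.search(pattern, subject_id)
    if not m:
        raise ValueError(
            f"cannot derive proteome tag from {subject_id!r} with pattern "
            f"{pattern!r}; supply a proteome map"
        )
    return m.group(1)


def read_blast_tab(
    path: str | Path,
    tag_pattern: str = DEFAULT_TAG_PATTERN,
    proteome_map: Mapping[str, str] | None = None,
) -> list[SearchHit]:
    """Parse BLAST tabular output (``-outfmt 6``) into :class:`SearchHit` s."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(OUTFMT6_COLUMNS):
        raise ValueError(
            f"{path}: expected >= {len(OUTFMT6_COLUMNS)} tab-separated columns "
            f"(BLAST outfmt 6), found {df.shape[1]}"
        )
    df.columns = OUTFMT6_COLUMNS + [
        f"extra{i}" for i in range(df.shape[1] - len(OUTFMT6_COLUMNS))
    ]
    return [
        SearchHit(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            proteome_tag=extract_proteome_tag(
                str(row.sseqid), tag_pattern, proteome_map
            ),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
        )
        for row in df.itertuples()
    ]


def select_one_per_proteome(hits: list[SearchHit]) -> list[SearchHit]:
    """Keep at most one hit per proteome.

    Selection is by highest bitscore, then lowest e-value, then
    lexicographically smallest subject id; the result is sorted by
    proteome tag.  Deterministic under input permutation.
    """
    best: dict[str, SearchHit] = {}
    for hit in hits:
        cur = best.get(hit.proteome_tag)
        if cur is None or _rank(hit) < _rank(cur):
            best[hit.proteome_tag] = hit
    return [best[tag] for tag in sorted(best)]


def _rank(hit: SearchHit) -> tuple[float, float, str]:
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def selection_frame(hits: list[SearchHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.proteome_tag, h.subject_id, h.query_id, h.bitscore, h.evalue)
            for h in hits
        ],
        columns=["proteome_tag", "subject_id", "query_id", "bitscore", "evalue"],
    )
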