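"""Global pairwise protein alignment.

The built-in aligner is a Gotoh dynamic program: global (Needleman-
Wunsch) alignment with BLOSUM62 substitution scores and affine gap
penalties (open 10, extend 0.5 per additional gapped residue, terminal
gaps penalized like internal ones).  Scores are kept in doubled integer
units internally so tie comparisons are exact.  Among co-optimal
traceback paths the aligner deterministically prefers gap states over
the diagonal while walking back from the C-terminus, which places gaps
as close to the C-terminal end of a repeat tract as possible -- a useful
canonical form when the gap could sit at any phase of a periodic region.

An adapter for an external command-line aligner (MUSCLE-style
``-in``/``-out`` or stdout-emitting tools such as MAFFT) is provided for
parity with published pipelines whose gap placement differs.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.Align import substitution_matrices

from pstrtool.seqio import ProteinRecord, read_fasta, write_fasta

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
NEG = -(10**9)

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM.alphabet)
_X_INDEX = _ALPHABET.index("X")
# doubled so that the 0.5 gap-extension penalty stays integral
_SCORES = (2 * np.asarray(_BLOSUM, dtype=np.int64)).astype(np.int32)
_OPEN2 = int(2 * GAP_OPEN)
_EXT2 = int(2 * GAP_EXTEND)

_ENCODE = np.full(128, _X_INDEX, dtype=np.int8)
for _i, _c in enumerate(_ALPHABET):
    _ENCODE[ord(_c)] = _i


@dataclass(frozen=True)
class AlignedPair:
    """A global pairwise alignment of two protein sequences.

    ``row_a``/``row_b`` are equal-length gapped strings; stripping the
    gaps reproduces the input sequences.  No column is gapped in both
    rows.  ``score`` is the alignment score (BLOSUM62, affine gaps).
    """

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows differ in length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == "-" and cb == "-":
                raise ValueError("column gapped in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    @property
    def seq_a(self) -> str:
        return self.row_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.row_b.replace("-", "")

    def col_to_pos(self, which: str) -> np.ndarray:
        """Per-column 1-based ungapped position in row ``which`` ('a'/'b');
        0 marks gap columns."""
        row = self.row_a if which == "a" else self.row_b
        out = np.zeros(len(row), dtype=np.int64)
        pos = 0
        for i, c in enumerate(row):
            if c != "-":
                pos += 1
                out[i] = pos
        return out

    def pos_to_col(self, which: str) -> np.ndarray:
        """Map from 1-based ungapped position to 0-based column (index 0 unused)."""
        row = self.row_a if which == "a" else self.row_b
        n = len(row) - row.count("-")
        out = np.zeros(n + 1, dtype=np.int64)
        pos = 0
        for i, c in enumerate(row):
            if c != "-":
                pos += 1
                out[pos] = i
        return out

    def swapped(self) -> "AlignedPair":
        return AlignedPair(
            id_a=self.id_b,
            id_b=self.id_a,
            row_a=self.row_b,
            row_b=self.row_a,
            score=self.score,
        )


@njit(cache=True)
def _fill(sa, sb, scores, open2, ext2):  # pragma: no cover - jit-compiled
    n = sa.shape[0]
    m = sb.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b, consumes a
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a, consumes b
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -open2 - (i - 1) * ext2
    for j in range(1, m + 1):
        Iy[0, j] = -open2 - (j - 1) * ext2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scores[sa[i - 1], sb[j - 1]]
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + s
            a = M[i - 1, j] - open2
            b = Ix[i - 1, j] - ext2
            c = Iy[i - 1, j] - open2
            Ix[i, j] = max(a, max(b, c))
            a = M[i, j - 1] - open2
            b = Iy[i, j - 1] - ext2
            c = Ix[i, j - 1] - open2
            Iy[i, j] = max(a, max(b, c))
    return M, Ix, Iy


def _traceback(sa_str: str, sb_str: str, M, Ix, Iy) -> tuple[str, str, int]:
    n, m = len(sa_str), len(sb_str)
    i, j = n, m
    # state preference at ties: Ix, Iy, then M (pushes gaps C-terminal)
    score2 = int(max(M[n, m], Ix[n, m], Iy[n, m]))
    state = "M"
    for s, mat in (("Ix", Ix), ("Iy", Iy), ("M", M)):
        if mat[n, m] == score2:
            state = s
            break
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ra.append(sa_str[i - 1])
            rb.append(sb_str[j - 1])
            target = M[i, j] - _pair_score(sa_str[i - 1], sb_str[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, val in (("Ix", Ix[i, j]), ("Iy", Iy[i, j]), ("M", M[i, j])):
                if val == target:
                    state = s
                    break
        elif state == "Ix":
            ra.append(sa_str[i - 1])
            rb.append("-")
            here = Ix[i, j]
            i -= 1
            if here == Ix[i, j] - _EXT2:
                state = "Ix"
            elif here == M[i, j] - _OPEN2:
                state = "M"
            else:
                state = "Iy"
        else:  # Iy
            ra.append("-")
            rb.append(sb_str[j - 1])
            here = Iy[i, j]
            j -= 1
            if here == Iy[i, j] - _EXT2:
                state = "Iy"
            elif here == M[i, j] - _OPEN2:
                state = "M"
            else:
                state = "Ix"
    return "".join(reversed(ra)), "".join(reversed(rb)), score2


def _pair_score(ca: str, cb: str) -> int:
    return int(_SCORES[_ENCODE[ord(ca)], _ENCODE[ord(cb)]])


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _align_builtin(a: ProteinRecord, b: ProteinRecord) -> AlignedPair:
    # canonical internal order makes align_pair(a, b) and align_pair(b, a)
    # column-identical after a row swap
    swap = (b.id, b.sequence) < (a.id, a.sequence)
    first, second = (b, a) if swap else (a, b)
    M, Ix, Iy = _fill(
        _encode(first.sequence), _encode(second.sequence), _SCORES, _OPEN2, _EXT2
    )
    row1, row2, score2 = _traceback(first.sequence, second.sequence, M, Ix, Iy)
    pair = AlignedPair(
        id_a=first.id, id_b=second.id, row_a=row1, row_b=row2, score=score2 / 2.0
    )
    return pair.swapped() if swap else pair


class ExternalAligner:
    """Adapter around an external pairwise alignment executable.

    ``template`` is a shell-style command with ``{exe}``, ``{input}`` and
    optionally ``{output}`` placeholders.  The tool is run on a temporary
    2-sequence FASTA and must produce aligned FASTA, either in the
    ``{output}`` file (MUSCLE convention, the default template) or on
    stdout when the template has no ``{output}`` (MAFFT convention).
    """

    def __init__(self, executable: str, template: str = "{exe} -in {input} -out {output}"):
        self.executable = executable
        self.template = template

    def align(self, a: ProteinRecord, b: ProteinRecord) -> AlignedPair:
        with tempfile.TemporaryDirectory(prefix="pstr_aln_") as tmp:
            inp = Path(tmp) / "pair.fasta"
            outp = Path(tmp) / "pair.aln.fasta"
            write_fasta([a, b], inp)
            cmd = self.template.format(exe=self.executable, input=inp, output=outp)
            proc = subprocess.run(
                shlex.split(cmd), capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"external aligner failed (exit {proc.returncode}): {proc.stderr.strip()}"
                )
            if "{output}" in self.template:
                text = outp.read_text()
            else:
                text = proc.stdout
            aligned = Path(tmp) / "parsed.fasta"
            aligned.write_text(text)
            rows = _parse_aligned_fasta(aligned, a, b)
        return rows

    def __call__(self, a: ProteinRecord, b: ProteinRecord) -> AlignedPair:
        return self.align(a, b)


def _parse_aligned_fasta(path: Path, a: ProteinRecord, b: ProteinRecord) -> AlignedPair:
    from Bio import SeqIO

    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = str(rec.seq).upper()
    if a.id not in rows or b.id not in rows:
        raise RuntimeError(
            f"external aligner output lacks ids {a.id!r}/{b.id!r}: got {sorted(rows)}"
        )
    pair = AlignedPair(id_a=a.id, id_b=b.id, row_a=rows[a.id], row_b=rows[b.id])
    if pair.seq_a != a.sequence or pair.seq_b != b.sequence:
        raise RuntimeError("external aligner output does not round-trip the inputs")
    return pair


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    backend: str | ExternalAligner = "builtin",
) -> AlignedPair:
    """Globally align two X-free protein sequences.

    ``backend`` is ``"builtin"`` (Gotoh/BLOSUM62, deterministic) or an
    :class:`ExternalAligner` instance.
    """
    for rec in (a, b):
        if not rec.sequence:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        if rec.has_x:
            raise ValueError(
                f"record {rec.id!r} contains 'X' residues; filter before aligning"
            )
    if backend == "builtin":
        return _align_builtin(a, b)
    if isinstance(backend, ExternalAligner):
        return backend.align(a, b)
    raise ValueError(f"unknown alignment backend: {backend!r}")


def all_pairs(
    records: list[ProteinRecord],
    backend: str | ExternalAligner = "builtin",
) -> Iterator[tuple[int, int, AlignedPair]]:
    """Align every unordered pair (input order, i < j); yields n(n-1)/2 pairs."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for all-versus-all comparison")
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            yield i, j, align_pair(records[i], records[j], backend=backend)
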