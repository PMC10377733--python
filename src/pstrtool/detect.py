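"""Sliding-window detection of protein short tandem repeats (pSTRs).

A pSTR is a maximal run of two or more identical, directly adjacent
residue units.  For every unit length k from 2 up to half the sequence
length, a window of length k is slid along the sequence and runs of two
or more consecutive equal k-mers are recorded.  All patterns are
reported, even when they overlap: cyclic rotations of a unit and
non-primitive units (e.g. ``PQPQ`` inside a ``PQ`` tract) count as
distinct repeats.  Unit length 1 (homorepeats) is excluded, because two
consecutive identical amino acids arise too easily by chance.

Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from pstrtool.seqio import ProteinRecord


@dataclass(frozen=True)
class PSTR:
    """One detected tandem repeat: ``unit`` repeated ``n_units`` times.

    ``start`` and ``end`` are 1-based inclusive positions of the first and
    last residue of the run; ``end == start + len(unit) * n_units - 1``.
    The run is maximal: it cannot be extended by one unit on either side.
    """

    seq_id: str
    unit: str
    start: int
    n_units: int

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def end(self) -> int:
        return self.start + len(self.unit) * self.n_units - 1

    def positions(self) -> range:
        """1-based residue positions covered by the run."""
        return range(self.start, self.end + 1)


def is_primitive(unit: str) -> bool:
    """True if ``unit`` is not itself a repetition of a shorter string."""
    k = len(unit)
    for d in range(1, k // 2 + 1):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def find_pstrs(
    record: ProteinRecord,
    min_unit: int = 2,
    max_unit: int | None = None,
    primitive_only: bool = False,
    exclude_homopolymer_units: bool = False,
) -> list[PSTR]:
    """Enumerate all pSTRs of ``record``.

    Parameters
    ----------
    record
        Sequence to scan.
    min_unit, max_unit
        Unit lengths considered; defaults 2 and ``len(record) // 2``.
    primitive_only
        Suppress units that are themselves periodic (``PQPQ``).
    exclude_homopolymer_units
        Suppress units composed of a single amino acid (``AA``); such
        runs restate a homorepeat at even length.

    Returns
    -------
    list of :class:`PSTR`, sorted by (start, unit length, unit).  Every
    reported run is maximal; a run strictly contained in a longer run of
    the identical unit string is suppressed, while rotations and
    non-primitive units are reported independently.
    """
    seq = record.sequence
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2 (homorepeats are excluded)")
    if max_unit is None:
        max_unit = L // 2
    if max_unit > L // 2:
        raise ValueError(f"max_unit {max_unit} exceeds floor(L/2) = {L // 2}")

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out: list[PSTR] = []
    for k in range(min_unit, max_unit + 1):
        # match[x] is True where the residue x residues ahead is identical;
        # a maximal True stretch [i, i+t) marks a region of length t+k that
        # is periodic with period k.
        match = arr[:-k] == arr[k:]
        if not match.any():
            continue
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for i, stop in zip(edges[::2], edges[1::2]):
            r = int(stop - i) + k  # length of the periodic region
            if r < 2 * k:
                continue
            i = int(i)
            # one maximal run per phase; later phases with < 2 full units
            # or repeating an already-covered phase are excluded.
            for j in range(i, min(i + k, i + r - 2 * k + 1)):
                unit = seq[j : j + k]
                n = (i + r - j) // k
                out.append(PSTR(seq_id=record.id, unit=unit, start=j + 1, n_units=n))

    if primitive_only:
        out = [p for p in out if is_primitive(p.unit)]
    if exclude_homopolymer_units:
        out = [p for p in out if len(set(p.unit)) > 1]
    out.sort(key=lambda p: (p.start, p.unit_length, p.unit))
    return out


def coverage_mask(record: ProteinRecord, pstrs: Iterable[PSTR]) -> np.ndarray:
    """Boolean mask (0-based) of residues inside at least one pSTR."""
    mask = np.zeros(len(record), dtype=bool)
    for p in pstrs:
        if p.seq_id != record.id:
            raise ValueError(
                f"pSTR annotated on {p.seq_id!r} does not belong to {record.id!r}"
            )
        mask[p.start - 1 : p.end] = True
    return mask


def residues_in_pstrs(record: ProteinRecord, pstrs: Iterable[PSTR]) -> float:
    """Fraction of residues participating in at least one pSTR.

    Each residue counts once however many runs cover it.
    """
    return float(coverage_mask(record, pstrs).sum()) / len(record)


def pstrs_to_frame(pstrs: Iterable[PSTR]) -> pd.DataFrame:
    """Tabulate pSTRs (columns: seq_id, unit, unit_length, start, end, n_units)."""
    rows = [
        (p.seq_id, p.unit, p.unit_length, p.start, p.end, p.n_units) for p in pstrs
    ]
    return pd.DataFrame(
        rows, columns=["seq_id", "unit", "unit_length", "start", "end", "n_units"]
    )
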