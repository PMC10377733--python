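"""Calling repeat unit-number variation from pairwise alignments.

When, in a global alignment of two homologous proteins, one or more
whole units of a pSTR align entirely to gaps in the partner while an
adjacent unit of the same repeat is conserved (identical residues in
both rows), the carrier holds extra repeat units relative to the
partner: an event of unit gain or loss.  Events are called per pairwise
alignment, deduplicated at the family level, and mapped onto a chosen
query sequence through the alignment column of the central residue of
the extra block.

Because a gap inside a periodic tract can sit at any phase with equal
alignment score, event coordinates are canonicalized to the C-terminal
phase of the containing run: the extra units are reported as the last
``n_extra_units`` units of the repeat.  The built-in aligner already
places gaps that way; the canonicalization makes event keys stable
under aligner backends that choose another phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pstrtool.align import AlignedPair, ExternalAligner, align_pair, all_pairs
from pstrtool.detect import PSTR, find_pstrs
from pstrtool.seqio import ProteinRecord

_GAP_OPPOSED = 0
_CONSERVED = 1
_OTHER = 2


@dataclass(frozen=True)
class UnitVariationEvent:
    """One gain/loss of repeat units between a carrier and a partner.

    The carrier holds ``n_extra_units`` more copies of ``unit`` than the
    partner; ``carrier_start`` is the 1-based first residue of the extra
    block (canonical C-terminal phase).  ``query_pos`` is filled by
    :func:`map_to_query`.
    """

    carrier_id: str
    partner_id: str
    unit: str
    carrier_start: int
    n_extra_units: int
    query_pos: int | None = None
    partner_ids: tuple[str, ...] = field(default=(), compare=False)

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Family-level deduplication key."""
        return (self.carrier_id, self.unit, self.carrier_start, self.n_extra_units)

    @property
    def central_carrier_pos(self) -> int:
        """Carrier position whose alignment column defines the mapping."""
        return self.carrier_start + (len(self.unit) * self.n_extra_units - 1) // 2

    def annotation(self) -> str:
        """Compact ``[UNIT(mapped position)]`` label."""
        pos = self.query_pos if self.query_pos is not None else "?"
        return f"[{self.unit}({pos})]"


def _validate_pstrs(seq: str, seq_id: str, pstrs: list[PSTR]) -> None:
    for p in pstrs:
        if p.seq_id != seq_id:
            raise ValueError(
                f"pSTR annotated on {p.seq_id!r} supplied for sequence {seq_id!r}"
            )
        if seq[p.start - 1 : p.end] != p.unit * p.n_units:
            raise ValueError(
                f"pSTR {p.unit!r}x{p.n_units}@{p.start} does not match sequence "
                f"{seq_id!r}; annotation not from this pair"
            )


def call_events(
    pair: AlignedPair,
    pstrs_a: list[PSTR],
    pstrs_b: list[PSTR],
) -> list[UnitVariationEvent]:
    """Call unit-variation events from one aligned pair.

    Each unit of each pSTR is classified as gap-opposed (every column
    opposite a gap in the partner row) or conserved (every column
    opposite the identical residue).  One event is emitted per maximal
    contiguous block of gap-opposed units immediately adjacent, within
    the pSTR, to at least one conserved unit.  Events are deduplicated
    within the pair on (carrier, unit, canonical start, block size).
    """
    seq_a, seq_b = pair.seq_a, pair.seq_b
    _validate_pstrs(seq_a, pair.id_a, pstrs_a)
    _validate_pstrs(seq_b, pair.id_b, pstrs_b)

    events: dict[tuple, UnitVariationEvent] = {}
    for which, pstrs, carrier_id, partner_id, carrier_seq in (
        ("a", pstrs_a, pair.id_a, pair.id_b, seq_a),
        ("b", pstrs_b, pair.id_b, pair.id_a, seq_b),
    ):
        pos2col = pair.pos_to_col(which)
        row_self = pair.row_a if which == "a" else pair.row_b
        row_other = pair.row_b if which == "a" else pair.row_a
        for p in pstrs:
            k = p.unit_length
            status = []
            for u in range(p.n_units):
                first = p.start + u * k
                cols = pos2col[first : first + k]
                other = [row_other[c] for c in cols]
                if all(c == "-" for c in other):
                    status.append(_GAP_OPPOSED)
                elif all(
                    o == row_self[c] for o, c in zip(other, cols)
                ):
                    status.append(_CONSERVED)
                else:
                    status.append(_OTHER)
            for ev in _blocks_to_events(p, status, carrier_id, partner_id):
                _check_carrier_block(carrier_seq, ev)
                events.setdefault(ev.key, ev)
    return sorted(
        events.values(),
        key=lambda e: (e.carrier_id, e.carrier_start, len(e.unit), e.unit),
    )


def _blocks_to_events(
    p: PSTR, status: list[int], carrier_id: str, partner_id: str
):
    k = p.unit_length
    n = len(status)
    u = 0
    while u < n:
        if status[u] != _GAP_OPPOSED:
            u += 1
            continue
        v = u
        while v + 1 < n and status[v + 1] == _GAP_OPPOSED:
            v += 1
        b = v - u + 1
        flanked = (u > 0 and status[u - 1] == _CONSERVED) or (
            v + 1 < n and status[v + 1] == _CONSERVED
        )
        if flanked:
            # canonical C-terminal phase: slide the block towards the
            # C-terminus while the unit beyond it is conserved, so any
            # gap placement the aligner chose maps to the same event
            u0, v0 = u, v
            while v0 + 1 < n and status[v0 + 1] == _CONSERVED:
                u0 += 1
                v0 += 1
            start = p.start + u0 * k
            yield UnitVariationEvent(
                carrier_id=carrier_id,
                partner_id=partner_id,
                unit=p.unit,
                carrier_start=start,
                n_extra_units=b,
            )
        u = v + 1


def _check_carrier_block(seq: str, ev: UnitVariationEvent) -> None:
    """The block plus its N-terminal conserved neighbour must spell the unit."""
    k = len(ev.unit)
    lo = ev.carrier_start - 1 - k
    hi = ev.carrier_start - 1 + k * ev.n_extra_units
    if lo < 0 or seq[lo:hi] != ev.unit * (ev.n_extra_units + 1):
        raise AssertionError(
            f"carrier block of event {ev.key} does not re-validate against "
            "the raw carrier sequence"
        )


@dataclass
class FamilyVariation:
    """Result of a family-level unit-variation scan.

    ``events`` are deduplicated across pairs on
    (carrier, unit, carrier_start, n_extra_units), each carrying the
    supporting partner ids; ``support`` is the symmetric n x n matrix of
    per-pair event counts (rows/columns in input order).
    """

    ids: list[str]
    events: list[UnitVariationEvent]
    support: np.ndarray
    query_id: str | None = None

    @property
    def n_pairs_with_events(self) -> int:
        return int((np.triu(self.support, k=1) > 0).sum())

    def events_frame(self) -> pd.DataFrame:
        rows = [
            (
                e.carrier_id,
                ",".join(e.partner_ids),
                e.unit,
                e.carrier_start,
                e.n_extra_units,
                e.query_pos if e.query_pos is not None else "",
            )
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "carrier_id",
                "partner_ids",
                "unit",
                "carrier_start",
                "n_extra_units",
                "query_pos",
            ],
        )

    def support_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support, index=self.ids, columns=self.ids)

    def position_track(self, query_length: int) -> pd.DataFrame:
        """Per-query-position count of mapped events."""
        counts = np.zeros(query_length + 1, dtype=int)
        for e in self.events:
            if e.query_pos is not None and 0 <= e.query_pos <= query_length:
                counts[e.query_pos] += 1
        return pd.DataFrame(
            {"query_pos": np.arange(1, query_length + 1), "n_events": counts[1:]}
        )


def map_to_query(
    event: UnitVariationEvent,
    carrier: ProteinRecord,
    query: ProteinRecord,
    backend: str | ExternalAligner = "builtin",
    _alignment: AlignedPair | None = None,
) -> int:
    """Map an event onto the query sequence.

    The carrier is aligned with the query; the query position in the
    column of the central residue of the extra block is returned.  When
    that column is a gap in the query, the nearest preceding non-gap
    query position is used (0 if none exists).
    """
    c = event.central_carrier_pos
    if carrier.id == query.id:
        return c
    pair = _alignment
    if pair is None:
        pair = align_pair(carrier, query, backend=backend)
    col = int(pair.pos_to_col("a")[c])
    col2pos_q = pair.col_to_pos("b")
    while col >= 0:
        if col2pos_q[col] > 0:
            return int(col2pos_q[col])
        col -= 1
    return 0


def call_family_events(
    records: list[ProteinRecord],
    backend: str | ExternalAligner = "builtin",
    min_unit: int = 2,
    max_unit: int | None = None,
    query: str | None = None,
    map_events: bool = True,
) -> FamilyVariation:
    """Run the full pipeline on a family of X-free sequences.

    All-versus-all pairwise alignments are scanned for unit-variation
    events, events are deduplicated across pairs, and (optionally) mapped
    onto the query sequence (default: the first input record).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to call unit variation")
    ids = [r.id for r in records]
    by_id = {r.id: r for r in records}
    if query is None:
        query_rec = records[0]
    else:
        if query not in by_id:
            raise ValueError(f"query id {query!r} is not among the input sequences")
        query_rec = by_id[query]

    pstrs = {
        r.id: find_pstrs(r, min_unit=min_unit, max_unit=max_unit) for r in records
    }
    n = len(records)
    support = np.zeros((n, n), dtype=int)
    merged: dict[tuple, UnitVariationEvent] = {}
    partners: dict[tuple, set[str]] = {}
    for i, j, pair in all_pairs(records, backend=backend):
        evs = call_events(pair, pstrs[records[i].id], pstrs[records[j].id])
        support[i, j] = support[j, i] = len(evs)
        for e in evs:
            merged.setdefault(e.key, e)
            partners.setdefault(e.key, set()).add(e.partner_id)

    order = {rid: idx for idx, rid in enumerate(ids)}
    events = []
    query_alignments: dict[str, AlignedPair] = {}
    for key in sorted(
        merged, key=lambda k: (order[k[0]], k[2], len(k[1]), k[1], k[3])
    ):
        e = replace(merged[key], partner_ids=tuple(sorted(partners[key])))
        if map_events:
            carrier = by_id[e.carrier_id]
            if carrier.id != query_rec.id and carrier.id not in query_alignments:
                query_alignments[carrier.id] = align_pair(
                    carrier, query_rec, backend=backend
                )
            qpos = map_to_query(
                e,
                carrier,
                query_rec,
                backend=backend,
                _alignment=query_alignments.get(carrier.id),
            )
            e = replace(e, query_pos=qpos)
        events.append(e)
    return FamilyVariation(
        ids=ids, events=events, support=support, query_id=query_rec.id
    )
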