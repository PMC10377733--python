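"""Synthetic homologous families with planted repeat-unit expansions.

The generator emulates a protein family that is identical except for
the number of units at a small set of repeat loci: a common random
background sequence carries, at each locus, a tract of a primitive unit
repeated a per-sequence number of times, optionally with point
substitutions outside the loci.  Because every difference between
family members is known by construction, the generator also emits a
machine-readable truth table of all unit-variation events (including
those over non-primitive super-units such as ``PQPQ`` inside a long
``PQ`` tract, which the detector reports as independent repeats) with
their canonical coordinates and query-mapped positions.  With zero
substitution noise the full pipeline must reproduce this table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pstrtool.composition import STANDARD_AA
from pstrtool.detect import is_primitive
from pstrtool.seqio import ProteinRecord, write_fasta
from pstrtool.variation import UnitVariationEvent


@dataclass(frozen=True)
class Locus:
    """One repeat locus: a tract of ``unit`` inserted before base
    position ``position`` (1-based), repeated ``counts[i]`` times in
    family member i."""

    position: int
    unit: str
    counts: tuple[int, ...]


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic family.

    ``substitution_rate`` applies per residue outside the repeat loci
    and their flanking unit-width windows, so the planted truth stays
    well defined.  ``query_index`` selects the member used as mapping
    reference (default: the first, matching the pipeline default).
    """

    seed: int
    n_seqs: int
    base_length: int
    loci: tuple[Locus, ...]
    substitution_rate: float = 0.0
    query_index: int = 0
    background: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ValueError("need n_seqs >= 2")
        if self.base_length < 1:
            raise ValueError("need base_length >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0 <= self.query_index < self.n_seqs:
            raise ValueError("query_index out of range")
        prev_pos = None
        prev_k = 0
        for loc in self.loci:
            k = len(loc.unit)
            if k < 2:
                raise ValueError(f"unit {loc.unit!r}: length must be >= 2")
            if not is_primitive(loc.unit):
                raise ValueError(f"unit {loc.unit!r} is not primitive")
            if not _junction_clean(loc.unit):
                raise ValueError(
                    f"unit {loc.unit!r} recreates a shorter repeat across "
                    "unit junctions; the planted truth would be ambiguous"
                )
            if len(loc.counts) != self.n_seqs:
                raise ValueError(
                    f"locus at {loc.position}: counts must have n_seqs entries"
                )
            if min(loc.counts) < 1:
                raise ValueError(f"locus at {loc.position}: unit counts must be >= 1")
            if not 1 <= loc.position <= self.base_length + 1:
                raise ValueError(f"locus position {loc.position} outside base")
            if prev_pos is not None and loc.position - prev_pos < prev_k + k:
                raise ValueError(
                    "overlapping loci: consecutive positions must be at least "
                    "the two unit lengths apart"
                )
            prev_pos, prev_k = loc.position, k


def _junction_clean(unit: str) -> bool:
    """True unless repeating ``unit`` creates a shorter repeat spanning
    the junction between copies (e.g. ``HVTTFHV`` + ``HVTTFHV`` spells
    ``...FHVHVT...``).  Such sub-repeats straddle the boundary between
    conserved and gap-opposed units and would add events the planted
    truth table cannot enumerate in closed form."""
    from pstrtool.detect import find_pstrs as _find
    from pstrtool.seqio import ProteinRecord as _PR

    k = len(unit)
    for run in _find(_PR("u2", unit * 2)):
        if run.unit_length < k and run.start <= k < run.end:
            return False
    return True


def _tract_starts(spec: FamilySpec, i: int) -> list[int]:
    """1-based start of each locus tract in sequence i."""
    starts = []
    offset = 0
    for loc in spec.loci:
        starts.append(loc.position + offset)
        offset += len(loc.unit) * loc.counts[i]
    return starts


def generate_family(
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], list[UnitVariationEvent]]:
    """Generate the family and its truth table of unit-variation events.

    Returns ``(records, truth)``; ``truth`` lists the deduplicated
    events (canonical C-terminal phase, supporting partners attached,
    query positions relative to the ``query_index`` member) that the
    alignment-based caller recovers at zero substitution noise.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(STANDARD_AA))
    p = None
    if spec.background is not None:
        p = np.asarray(spec.background, dtype=float)
        p = p / p.sum()
    base = rng.choice(alphabet, size=spec.base_length, p=p)
    _guard_flanks(base, spec)

    protected = np.zeros(spec.base_length, dtype=bool)
    for loc in spec.loci:
        k = len(loc.unit)
        lo = max(0, loc.position - 1 - k)
        hi = min(spec.base_length, loc.position - 1 + k)
        protected[lo:hi] = True

    records = []
    for i in range(spec.n_seqs):
        seq_base = base.copy()
        if spec.substitution_rate > 0:
            hit = (rng.random(spec.base_length) < spec.substitution_rate) & ~protected
            for idx in np.flatnonzero(hit):
                choices = [c for c in STANDARD_AA if c != seq_base[idx]]
                seq_base[idx] = choices[int(rng.integers(len(choices)))]
        parts = []
        prev = 0
        for loc in spec.loci:
            parts.append("".join(seq_base[prev : loc.position - 1]))
            parts.append(loc.unit * loc.counts[i])
            prev = loc.position - 1
        parts.append("".join(seq_base[prev:]))
        records.append(
            ProteinRecord(
                id=f"seq{i + 1}",
                sequence="".join(parts),
                description=f"seq{i + 1} synthetic family seed={spec.seed}",
            )
        )

    truth = _truth_events(spec, records)
    return records, truth


def _guard_flanks(base: np.ndarray, spec: FamilySpec) -> None:
    """Pin the phase of every tract and clean its boundaries.

    Two kinds of background coincidence would make the planted truth
    ambiguous: (1) the residue immediately before a tract equalling the
    unit's last residue (or the one after it the unit's first), which
    lets maximal runs and optimal gap placements slide past the locus by
    a rotation; (2) any chance repeat run straddling a tract boundary
    (e.g. a flank starting with the unit's last two residues), which
    plants an extra, unintended repeat across the gap region.  Both are
    removed by deterministically rewriting the single flank residue at
    the offending boundary; a fixpoint loop covers interactions between
    neighbouring loci."""
    for _ in range(4):
        dirty = False
        for loc in spec.loci:
            k = len(loc.unit)
            pos0 = loc.position - 1
            tail = loc.unit * min(max(max(loc.counts), 2), 5)
            win = 2 * k + 12
            if pos0 - 1 >= 0:
                head = "".join(base[max(0, pos0 - win) : pos0])
                dirty |= _clean_boundary(
                    base,
                    mut_index=pos0 - 1,
                    context=head + tail,
                    ctx_idx=len(head) - 1,
                    boundary=len(head),
                    forbidden={loc.unit[-1]},
                )
            if pos0 < len(base):
                flank = "".join(base[pos0 : pos0 + win])
                dirty |= _clean_boundary(
                    base,
                    mut_index=pos0,
                    context=tail + flank,
                    ctx_idx=len(tail),
                    boundary=len(tail),
                    forbidden={loc.unit[0]},
                )
        if not dirty:
            return
    raise RuntimeError("could not clean tract boundaries; adjust the family spec")


def _clean_boundary(
    base: np.ndarray,
    mut_index: int,
    context: str,
    ctx_idx: int,
    boundary: int,
    forbidden: set[str],
) -> bool:
    """Rewrite ``base[mut_index]`` (at ``ctx_idx`` within ``context``) so
    that its letter avoids ``forbidden`` and no repeat run crosses the
    boundary (1-based: run.start <= boundary < run.end).  The current
    letter is kept whenever it already qualifies.  Returns True iff a
    mutation was made."""
    from pstrtool.detect import find_pstrs as _find
    from pstrtool.seqio import ProteinRecord as _PR

    candidates = [str(base[mut_index])] + [
        c for c in STANDARD_AA if c != base[mut_index]
    ]
    for letter in candidates:
        if letter in forbidden:
            continue
        trial = context[:ctx_idx] + letter + context[ctx_idx + 1 :]
        runs = _find(_PR("ctx", trial)) if len(trial) >= 4 else []
        if not any(r.start <= boundary < r.end for r in runs):
            if letter != base[mut_index]:
                base[mut_index] = letter
                return True
            return False
    raise RuntimeError("no residue choice cleans the tract boundary")


def _truth_events(
    spec: FamilySpec, records: list[ProteinRecord]
) -> list[UnitVariationEvent]:
    n = spec.n_seqs
    starts = [_tract_starts(spec, i) for i in range(n)]
    q = spec.query_index
    merged: dict[tuple, dict] = {}
    for li, loc in enumerate(spec.loci):
        k = len(loc.unit)
        for i in range(n):
            m = loc.counts[i]
            for j in range(n):
                pj = loc.counts[j]
                if j == i or m <= pj:
                    continue
                # every super-unit length t*k yields one event; the
                # canonical extra block always starts right after the
                # partner's share of the tract
                for t in range(1, min(pj, m - pj) + 1):
                    carrier_start = starts[i][li] + pj * k
                    n_extra = (m - pj) // t
                    key = (records[i].id, loc.unit * t, carrier_start, n_extra)
                    entry = merged.setdefault(
                        key,
                        {
                            "partners": set(),
                            "qpos": _map_truth(
                                spec, starts, li, i, pj, t, n_extra
                            ),
                        },
                    )
                    entry["partners"].add(records[j].id)
    order = {rec.id: idx for idx, rec in enumerate(records)}
    events = []
    for key in sorted(
        merged, key=lambda kk: (order[kk[0]], kk[2], len(kk[1]), kk[1], kk[3])
    ):
        carrier_id, unit, carrier_start, n_extra = key
        events.append(
            UnitVariationEvent(
                carrier_id=carrier_id,
                partner_id=sorted(merged[key]["partners"])[0],
                unit=unit,
                carrier_start=carrier_start,
                n_extra_units=n_extra,
                query_pos=merged[key]["qpos"],
                partner_ids=tuple(sorted(merged[key]["partners"])),
            )
        )
    return events


def _map_truth(
    spec: FamilySpec,
    starts: list[list[int]],
    li: int,
    carrier: int,
    p_partner: int,
    t: int,
    n_extra: int,
) -> int:
    """Query position of the event centre under C-terminal gap placement."""
    loc = spec.loci[li]
    k = len(loc.unit)
    q = spec.query_index
    q_units = loc.counts[q]
    offset = p_partner * k + (t * k * n_extra - 1) // 2
    if carrier == q or offset < q_units * k:
        return starts[q][li] + offset
    return starts[q][li] + q_units * k - 1


def write_family(
    records: list[ProteinRecord],
    truth: list[UnitVariationEvent],
    outdir: str | Path,
    prefix: str = "family",
) -> tuple[Path, Path]:
    """Emit the family FASTA and the truth table TSV (events schema)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{prefix}.fasta"
    tsv = outdir / f"{prefix}.truth.tsv"
    write_fasta(records, fasta)
    rows = [
        (
            e.carrier_id,
            ",".join(e.partner_ids),
            e.unit,
            e.carrier_start,
            e.n_extra_units,
            e.query_pos,
        )
        for e in truth
    ]
    pd.DataFrame(
        rows,
        columns=[
            "carrier_id",
            "partner_ids",
            "unit",
            "carrier_start",
            "n_extra_units",
            "query_pos",
        ],
    ).to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def random_family_spec(
    seed: int,
    n_seqs: int | None = None,
    base_length: int = 240,
    max_loci: int = 3,
    max_units: int = 5,
) -> FamilySpec:
    """Draw a valid random :class:`FamilySpec`.

    Defaults emulate a small ortholog family: 2-6 members of background
    length 240 (full length roughly the 200-300 residue range typical of
    curated ortholog sets), 1-3 repeat loci with primitive units of 2-7
    residues and 1-5 units per member.
    """
    rng = np.random.default_rng(seed)
    if n_seqs is None:
        n_seqs = int(rng.integers(2, 7))
    n_loci = int(rng.integers(1, max_loci + 1))
    # place loci in equal-width bands so spacing constraints always hold
    band = base_length // n_loci
    loci = []
    for li in range(n_loci):
        unit = _random_primitive_unit(rng)
        position = li * band + int(rng.integers(10, max(11, band // 2)))
        counts = tuple(int(c) for c in rng.integers(1, max_units + 1, size=n_seqs))
        loci.append(Locus(position=position, unit=unit, counts=counts))
    return FamilySpec(
        seed=int(rng.integers(2**31)),
        n_seqs=n_seqs,
        base_length=base_length,
        loci=tuple(loci),
        substitution_rate=0.0,
    )


def _random_primitive_unit(rng: np.random.Generator) -> str:
    alphabet = list(STANDARD_AA)
    while True:
        k = int(rng.integers(2, 8))
        unit = "".join(rng.choice(alphabet, size=k))
        if is_primitive(unit) and _junction_clean(unit):
            return unit
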