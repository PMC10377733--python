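"""Proteome-level pSTR composition statistics.

For a proteome this module computes the fraction of residues lying in at
least one pSTR (residue coverage) and compares amino-acid usage inside
pSTRs with the background usage over all residues.  Frequencies are
taken over the 20 standard amino acids; rarer letters (B, Z, U, O, J)
stay in the coverage denominator but are left out of the frequency
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from pstrtool.detect import coverage_mask, find_pstrs
from pstrtool.seqio import ProteinRecord, filter_x_sequences

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class CompositionStats:
    """Coverage and amino-acid usage of one proteome.

    ``background_freq`` and ``pstr_freq`` are 20-vectors over
    :data:`STANDARD_AA` summing to 1; when the proteome has no pSTR
    residues at all, ``pstr_freq`` is all zeros and ``has_pstr_residues``
    is False.
    """

    label: str
    n_sequences_used: int
    n_sequences_dropped_x: int
    coverage: float
    background_freq: pd.Series
    pstr_freq: pd.Series
    has_pstr_residues: bool = True

    def __post_init__(self) -> None:
        for name, vec in (("background", self.background_freq),
                          ("pstr", self.pstr_freq)):
            if (vec < 0).any():
                raise ValueError(f"{name} frequencies must be non-negative")
            total = float(vec.sum())
            expect = 1.0 if (name == "background" or self.has_pstr_residues) else 0.0
            if abs(total - expect) > 1e-9:
                raise ValueError(f"{name} frequencies sum to {total}, not {expect}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")


def _count_standard(counter: np.ndarray, seq_slice: str) -> None:
    for aa in seq_slice:
        idx = _AA_INDEX.get(aa)
        if idx is not None:
            counter[idx] += 1


def proteome_composition(
    records: list[ProteinRecord],
    label: str = "",
    filter_x: bool = True,
    min_unit: int = 2,
) -> CompositionStats:
    """Aggregate pSTR coverage and composition over a set of sequences.

    Coverage is residue-count weighted over the whole proteome (total
    covered residues / total residues), each residue counted once no
    matter how many overlapping pSTRs contain it.
    """
    dropped: list[str] = []
    if filter_x:
        records, dropped = filter_x_sequences(records)
    if not records:
        raise ValueError("no sequences left after filtering; cannot compute stats")

    total_len = 0
    covered = 0
    bg = np.zeros(len(STANDARD_AA), dtype=np.int64)
    instr = np.zeros(len(STANDARD_AA), dtype=np.int64)
    for rec in records:
        pstrs = find_pstrs(rec, min_unit=min_unit)
        mask = coverage_mask(rec, pstrs)
        total_len += len(rec)
        covered += int(mask.sum())
        _count_standard(bg, rec.sequence)
        _count_standard(instr, "".join(c for c, m in zip(rec.sequence, mask) if m))

    background = pd.Series(bg, index=list(STANDARD_AA), dtype=float)
    background /= background.sum()
    has_pstr = instr.sum() > 0
    pstr_freq = pd.Series(instr, index=list(STANDARD_AA), dtype=float)
    if has_pstr:
        pstr_freq /= pstr_freq.sum()
    return CompositionStats(
        label=label,
        n_sequences_used=len(records),
        n_sequences_dropped_x=len(dropped),
        coverage=covered / total_len,
        background_freq=background,
        pstr_freq=pstr_freq,
        has_pstr_residues=bool(has_pstr),
    )


def stats_frame(stats: Iterable[CompositionStats]) -> pd.DataFrame:
    """One row per proteome: coverage plus both 20-dim frequency vectors."""
    rows = []
    for s in stats:
        row: dict[str, object] = {
            "label": s.label,
            "n_sequences_used": s.n_sequences_used,
            "n_sequences_dropped_x": s.n_sequences_dropped_x,
            "coverage": s.coverage,
            "has_pstr_residues": s.has_pstr_residues,
        }
        for aa in STANDARD_AA:
            row[f"bg_{aa}"] = s.background_freq[aa]
        for aa in STANDARD_AA:
            row[f"pstr_{aa}"] = s.pstr_freq[aa]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_composition(stats: list[CompositionStats], path: str) -> None:
    """Bar panel of per-proteome coverage plus paired usage panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    labels = [s.label for s in stats]
    axes[0].bar(labels, [100 * s.coverage for s in stats], color="#88c")
    axes[0].set_ylabel("% residues in pSTRs")
    axes[0].tick_params(axis="x", rotation=90)
    for ax, attr, title in (
        (axes[1], "background_freq", "background usage"),
        (axes[2], "pstr_freq", "usage in pSTRs"),
    ):
        mat = np.vstack([getattr(s, attr).to_numpy() for s in stats])
        im = ax.imshow(mat, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(STANDARD_AA)), list(STANDARD_AA))
        ax.set_yticks(range(len(labels)), labels)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
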