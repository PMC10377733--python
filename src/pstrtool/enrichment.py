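"""Set-overlap enrichment statistics.

Given a universe of proteins, a subset selected by thresholding an
external per-protein score (e.g. a liquid-liquid phase-separation
propensity in [0, 1]), and a subset of interest (proteins in families
with pSTR unit variation), the overlap is tested with the one-sided
hypergeometric upper tail: the probability of drawing at least the
observed number of selected proteins when sampling the family set
without replacement from the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy import stats


@dataclass(frozen=True)
class OverlapTable:
    """Counts for a 2x2 overlap test.

    ``n_selected`` proteins of the ``n_universe`` pass the score cutoff;
    ``n_family`` proteins belong to families with unit variation, of
    which ``n_overlap`` also pass the cutoff.
    """

    n_universe: int
    n_selected: int
    n_family: int
    n_overlap: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n_overlap
            and self.n_overlap <= min(self.n_selected, self.n_family)
            and max(self.n_selected, self.n_family) <= self.n_universe
        )
        if not ok:
            raise ValueError(
                "invalid overlap table: need 0 <= n_overlap <= "
                "min(n_selected, n_family) <= n_universe, got "
                f"{self!r}"
            )


def threshold_scores(scores: Mapping[str, float], cutoff: float) -> set[str]:
    """Ids whose score is >= ``cutoff`` (inclusive threshold convention)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    for key, val in scores.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"score for {key!r} outside [0, 1]: {val}")
    return {key for key, val in scores.items() if val >= cutoff}


def enrichment_pvalue(table: OverlapTable, two_sided: bool = False) -> float:
    """Hypergeometric overlap p-value.

    Default is the one-sided upper tail P(X >= n_overlap) for X drawn
    from Hypergeometric(n_universe, n_selected, n_family) -- the
    enrichment direction.  ``two_sided=True`` instead returns the
    two-sided Fisher exact p-value of the corresponding 2x2 table.
    """
    if two_sided:
        t = [
            [table.n_overlap, table.n_family - table.n_overlap],
            [
                table.n_selected - table.n_overlap,
                table.n_universe - table.n_selected - table.n_family + table.n_overlap,
            ],
        ]
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    return float(
        stats.hypergeom.sf(
            table.n_overlap - 1, table.n_universe, table.n_selected, table.n_family
        )
    )
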