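"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (triple loops, direct tail sums) kept
separate from the package so they cannot share a bug with the code under
test.
"""

from math import comb


def brute_pstrs(seq: str, min_unit: int = 2):
    """All maximal runs of >= 2 identical adjacent units, O(L^3).

    Returns (unit, 1-based start, n_units) tuples, sorted like the
    detector output.
    """
    L = len(seq)
    out = []
    for k in range(min_unit, L // 2 + 1):
        for start in range(0, L - 2 * k + 1):
            unit = seq[start : start + k]
            if start >= k and seq[start - k : start] == unit:
                continue  # not maximal on the left
            n = 1
            while seq[start + n * k : start + (n + 1) * k] == unit:
                n += 1
            if n >= 2:
                out.append((unit, start + 1, n))
    out.sort(key=lambda t: (t[1], len(t[0]), t[0]))
    return out


def brute_coverage(seq: str):
    """Fraction of residues in at least one repeat, via a position set."""
    covered = set()
    for unit, start, n in brute_pstrs(seq):
        covered.update(range(start, start + len(unit) * n))
    return len(covered) / len(seq)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += comb(K, x) * comb(N - K, n - x)
    return acc / total
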