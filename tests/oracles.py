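"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithmic machinery: windows are
enumerated naively, Fitch lengths come from exhaustive labeling enumeration,
and identities are computed with plain Python loops.
"""
from __future__ import annotations

import itertools
from fractions import Fraction

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(s))


def _mismatch(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x not in COMP)


def _qualifies(mism: int, length: int, ident: Fraction) -> bool:
    return length * (ident.denominator - ident.numerator) >= ident.denominator * mism


def brute_dispersed(seq: str, min_len: int = 30, min_identity: float = 0.9):
    """All containment-maximal qualifying same-strand pairs, O(n^3)-ish."""
    ident = Fraction(min_identity).limit_denominator(10_000)
    n = len(seq)
    qual = []
    for i in range(n):
        for j in range(i + 1, n):
            maxL = min(n - j, n - i)
            mism = 0
            for L in range(1, maxL + 1):
                a, b = seq[i + L - 1], seq[j + L - 1]
                if a != b or a not in COMP:
                    mism += 1
                if L >= min_len and _qualifies(mism, L, ident):
                    qual.append((i, j, L))
    return _maximal_pairs(qual)


def brute_palindromic(seq: str, min_arm: int = 20, max_gap: int = 3000,
                      min_identity: float = 0.9):
    """All containment-maximal qualifying arm pairs (arm2 = revcomp of arm1).

    Enumerated as matches between the sequence and its reverse complement,
    with incremental mismatch counts along each start pair."""
    ident = Fraction(min_identity).limit_denominator(10_000)
    n = len(seq)
    rc = revcomp(seq)
    qual = set()
    for p in range(n):
        for q in range(n):
            mism = 0
            for L in range(1, min(n - p, n - q) + 1):
                a, b = seq[p + L - 1], rc[q + L - 1]
                if a != b or a not in COMP:
                    mism += 1
                if L < min_arm or not _qualifies(mism, L, ident):
                    continue
                i, j = p, n - q - L  # genome starts of the two arms
                if j < i:
                    i, j = j, i
                gap = j - i - L
                if 0 <= gap <= max_gap:
                    qual.add((i, j, L))
    return _maximal_pairs(qual)


def _maximal_pairs(qual):
    out = []
    qs = set(qual)
    for i, j, L in qs:
        contained = any(
            (i2, j2, L2) != (i, j, L)
            and i2 <= i and i + L <= i2 + L2 and j2 <= j and j + L <= j2 + L2
            for i2, j2, L2 in qs
        )
        if not contained:
            out.append((i, j, L))
    return sorted(out)


def brute_tandem_intervals(seq: str, min_unit: int = 15, min_identity: float = 0.9,
                           max_unit: int = 100):
    """Genomic intervals covered by a qualifying tandem array (adjacent-copy
    identity >= cutoff), for comparing coverage with the tandem finder."""
    ident = Fraction(min_identity).limit_denominator(10_000)
    n = len(seq)
    covered = set()
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        for i in range(n - 2 * u + 1):
            if _qualifies(_mismatch(seq[i : i + u], seq[i + u : i + 2 * u]), u, ident):
                covered.update(range(i, i + 2 * u))
    return covered


# ---------------------------------------------------------------------------
# parsimony oracles


def fitch_by_enumeration(edges, n_taxa, leaf_states):
    """Minimum changes over all internal labelings (states as frozensets of
    observed symbols; wildcard leaves range over every observed symbol)."""
    symbols = sorted({s for st in leaf_states for s in st})
    internal = sorted({x for e in edges for x in e if x >= n_taxa})
    best = None
    leaf_choices = [sorted(st) for st in leaf_states]
    for leaf_combo in itertools.product(*leaf_choices):
        for combo in itertools.product(symbols, repeat=len(internal)):
            assign = dict(zip(internal, combo))
            for leaf, s in enumerate(leaf_combo):
                assign[leaf] = s
            changes = sum(1 for u, v in edges if assign[u] != assign[v])
            if best is None or changes < best:
                best = changes
    return best


def matrix_length_by_enumeration(topology, matrix):
    """Sum of per-character enumeration minima on one topology."""
    n = topology.n_taxa
    edges = topology.edges
    total = 0
    for j in range(matrix.n_chars):
        col = [r[j] for r in matrix.subset(list(topology.taxa)).rows]
        states = sorted({c for c in col if c not in "?-"})
        if len(states) <= 1:
            continue
        leaf_states = [
            frozenset([c]) if c not in "?-" else frozenset(states) for c in col
        ]
        total += fitch_by_enumeration(edges, n, leaf_states)
    return total


def ols_normal_equations(x, y):
    """Closed-form simple OLS (slope, intercept, r_squared)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ym = sy / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ym) ** 2 for yi in y)
    r2 = 1 - ss_res / ss_tot if ss_tot else float("nan")
    return slope, intercept, r2
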