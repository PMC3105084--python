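"""Diagonal match engine shared by the dispersed and palindromic repeat finders.

Model: an ungapped pair of equal-length segments qualifies when its Hamming
identity (matches/length, ambiguity codes never match) is >= the cutoff and
its length >= the minimum.  Reported pairs are *containment-maximal*: a
qualifying window is dropped when a strictly containing window (same diagonal
or nested across diagonals) also qualifies.

Two code paths produce identical results on their shared domain:

* small inputs: every diagonal is scanned exhaustively;
* genome-scale inputs: diagonals are anchored by exact k-mer seeds (k chosen
  by pigeonhole so that every qualifying minimum-length window must contain a
  seed), and the exact window computation runs on a padded neighbourhood of
  the seeds.  Repeat copies longer than ``max_len`` are outside the design
  envelope of the seeded path.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._seq import encode, revcomp

SMALL_INPUT = 6000  # below this total size, scan every diagonal exhaustively


@dataclass(frozen=True)
class PairMatch:
    """Maximal qualifying window: s1[p:p+length] vs s2[q:q+length]."""

    p: int
    q: int
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length


def _identity_fraction(min_identity: float) -> Fraction:
    return Fraction(min_identity).limit_denominator(10_000)


def maximal_windows(mismatch: np.ndarray, min_len: int, ident: Fraction):
    """Containment-maximal qualifying windows along one diagonal.

    ``mismatch`` is a 0/1 array; a window [a, b] qualifies iff
    b-a+1 >= min_len and mismatches(a,b)/(b-a+1) <= 1-ident.  Returns a list
    of (a, b, n_mismatch), exact via integer arithmetic.
    """
    m = len(mismatch)
    if m < min_len:
        return []
    num, den = ident.numerator, ident.denominator
    pref = np.concatenate([[0], np.cumsum(mismatch, dtype=np.int64)])
    # qualify(a, b)  <=>  c[b+1] <= c[a]  with  c[i] = den*pref[i] - (den-num)*i
    c = den * pref - (den - num) * np.arange(m + 1, dtype=np.int64)
    order = np.argsort(c, kind="stable")
    svals = c[order]
    prefmax_idx = np.maximum.accumulate(order)
    starts = np.arange(0, m - min_len + 1)
    pos = np.searchsorted(svals, c[starts], side="right") - 1
    J = prefmax_idx[np.clip(pos, 0, None)]
    valid = (pos >= 0) & (J >= starts + min_len)
    out = []
    best = -1
    for a in range(len(starts)):
        if not valid[a]:
            continue
        j = int(J[a])
        if j > best:  # record value of J => containment-maximal on this diagonal
            b = j - 1
            out.append((a, b, int(pref[j] - pref[a])))
            best = j
    return out


def _filter_contained(matches: list[PairMatch]) -> list[PairMatch]:
    """Drop pairs whose both windows are strictly nested inside another pair's."""
    keep = []
    ms = sorted(matches, key=lambda t: -t.length)
    for cand in ms:
        contained = False
        for big in ms:
            if big.length <= cand.length:
                break
            if (
                big.p <= cand.p
                and big.p + big.length >= cand.p + cand.length
                and big.q <= cand.q
                and big.q + big.length >= cand.q + cand.length
            ):
                contained = True
                break
        if not contained:
            keep.append(cand)
    return sorted(keep, key=lambda t: (t.p, t.q))


def _seed_k(min_len: int, ident: Fraction) -> int:
    """Pigeonhole-complete seed length: any qualifying min_len-window with at
    most f mismatches contains an exact run of ceil((min_len-f)/(f+1))."""
    f = int((1 - ident) * min_len)
    return max(4, -(-(min_len - f) // (f + 1)))


def _diag_mismatch(c1: np.ndarray, c2: np.ndarray, d: int):
    """Mismatch array along diagonal d (= p - q) plus the p-offset of index 0."""
    if d >= 0:
        a, b = c1[d:], c2[: len(c1) - d if len(c1) - d <= len(c2) else len(c2)]
        off = d
    else:
        a, b = c1[: len(c2) + d], c2[-d:]
        off = 0
    m = min(len(a), len(b))
    a, b = a[:m], b[:m]
    return ((a != b) | (a >= 4)).astype(np.int8), off


def scan_pairs(
    s1: str,
    s2: str | None = None,
    min_len: int = 30,
    min_identity: float = 0.90,
    max_len: int = 1000,
) -> list[PairMatch]:
    """All containment-maximal qualifying pairs between s1 and s2.

    With ``s2=None`` the scan is s1 against itself: the trivial self-diagonal
    is excluded and each pair is reported once with p < q.
    """
    self_mode = s2 is None
    if self_mode:
        s2 = s1
    ident = _identity_fraction(min_identity)
    c1, c2 = encode(s1), encode(s2)
    n1, n2 = len(c1), len(c2)
    if n1 < min_len or n2 < min_len:
        return []

    raw: list[PairMatch] = []
    if n1 + n2 <= SMALL_INPUT:
        dlo, dhi = -(n2 - min_len), n1 - min_len
        for d in range(dlo, dhi + 1):
            if self_mode and d <= 0:
                continue  # p < q pairs live on positive diagonals
            mism, off = _diag_mismatch(c1, c2, d)
            for a, b, nm in maximal_windows(mism, min_len, ident):
                raw.append(PairMatch(off + a, off + a - d, b - a + 1, nm))
    else:
        raw = _scan_seeded(c1, c2, min_len, ident, max_len, self_mode)

    if self_mode:
        raw = [
            PairMatch(min(m.p, m.q), max(m.p, m.q), m.length, m.mismatches)
            for m in raw
            if m.p != m.q
        ]
        raw = list(dict.fromkeys(raw))
    return _filter_contained(raw)


def _scan_seeded(c1, c2, min_len, ident, max_len, self_mode):
    n1, n2 = len(c1), len(c2)
    k = _seed_k(min_len, ident)
    f = int((1 - ident) * min_len)
    # k-mer ids (positions containing ambiguity codes get no seed)
    def kmer_ids(c):
        ids = np.zeros(len(c) - k + 1, dtype=np.int64)
        ok = np.ones(len(c) - k + 1, dtype=bool)
        for i in range(k):
            w = c[i : len(c) - k + 1 + i]
            ids = ids * 4 + np.minimum(w, 3)
            ok &= w < 4
        return ids, ok

    ids1, ok1 = kmer_ids(c1)
    ids2, ok2 = kmer_ids(c2)
    p1 = np.nonzero(ok1)[0]
    order = np.argsort(ids1[p1], kind="stable")
    sorted_ids = ids1[p1][order]
    sorted_pos = p1[order]
    q2 = np.nonzero(ok2)[0]
    left = np.searchsorted(sorted_ids, ids2[q2], side="left")
    right = np.searchsorted(sorted_ids, ids2[q2], side="right")
    lens = right - left
    hit = lens > 0
    q2, left, lens = q2[hit], left[hit], lens[hit]
    tot = int(lens.sum())
    if tot == 0:
        return []
    cum = np.cumsum(lens)
    flat = np.arange(tot) + np.repeat(left - np.concatenate([[0], cum[:-1]]), lens)
    sp = sorted_pos[flat]
    sq = np.repeat(q2, lens)
    if self_mode:
        m = sp < sq
        sp, sq = sp[m], sq[m]
    if len(sp) == 0:
        return []

    # anchor filter: keep seeds with some min_len-window (containing the seed)
    # holding at most f mismatches -- necessary for any qualifying window
    span = min_len + (min_len - k)  # positions to inspect around the seed
    offs = np.arange(-(min_len - k), min_len)
    keep_chunks = []
    for lo_i in range(0, len(sp), 200_000):
        cp = sp[lo_i : lo_i + 200_000]
        cq = sq[lo_i : lo_i + 200_000]
        pi = cp[:, None] + offs[None, :]
        qi = cq[:, None] + offs[None, :]
        inb = (pi >= 0) & (pi < n1) & (qi >= 0) & (qi < n2)
        a = np.where(inb, c1[np.clip(pi, 0, n1 - 1)], 9)
        b = np.where(inb, c2[np.clip(qi, 0, n2 - 1)], 9)
        mm = ((a != b) | (a >= 4)).astype(np.int16)
        cs = np.concatenate(
            [np.zeros((len(cp), 1), dtype=np.int16), np.cumsum(mm, axis=1)], axis=1
        )
        wins = cs[:, min_len:] - cs[:, : span - min_len + 1]
        keep_chunks.append((wins <= f).any(axis=1))
    survive = np.concatenate(keep_chunks)
    sp, sq = sp[survive], sq[survive]
    if len(sp) == 0:
        return []

    pad = int((1 - float(ident)) / float(ident) * max_len) + min_len + max_len
    by_diag: dict[int, list[int]] = {}
    for p, q in zip(sp.tolist(), sq.tolist()):
        by_diag.setdefault(p - q, []).append(p)
    out = []
    for d, ps in by_diag.items():
        mism, off = _diag_mismatch(c1, c2, d)
        m = len(mism)
        lo = max(0, min(ps) - off - pad)
        hi = min(m, max(ps) - off + k + pad)
        while True:
            wins_out = maximal_windows(mism[lo:hi], min_len, ident)
            touches = any(
                (a == 0 and lo > 0) or (b == hi - lo - 1 and hi < m)
                for a, b, _ in wins_out
            )
            if not touches:
                break
            lo, hi = max(0, lo - pad), min(m, hi + pad)
        for a, b, nm in wins_out:
            p = off + lo + a
            out.append(PairMatch(p, p - d, b - a + 1, nm))
    return out


def palindromic_pairs(
    seq: str, min_arm: int = 20, max_gap: int = 3000, min_identity: float = 0.90,
    max_len: int = 1000,
) -> list[PairMatch]:
    """Arm pairs where one arm matches the reverse complement of the other.

    Returned as genome-coordinate pairs (p = first arm start, q = second arm
    start, q >= p + length, gap = q - p - length <= max_gap).
    """
    n = len(seq)
    raw = scan_pairs(seq, revcomp(seq), min_len=min_arm, min_identity=min_identity,
                     max_len=max_len)
    out = []
    for m in raw:
        j = n - m.q - m.length  # genome start of the mirrored arm
        p, q = (m.p, j) if m.p <= j else (j, m.p)
        gap = q - p - m.length
        if 0 <= gap <= max_gap:
            out.append(PairMatch(p, q, m.length, m.mismatches))
    return sorted(set(out), key=lambda t: (t.p, t.q))
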