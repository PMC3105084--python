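"""Detection of the quadripartite plastome architecture and junction geometry.

A plastome carries two identical inverted-repeat arms (IRa, IRb) separated by
the large and small single-copy regions (LSC, SSC).  The detector finds the
maximal pair of disjoint segments where one arm equals the reverse complement
of the other (exact by default, Hamming-tolerant optionally), labels the
shorter inter-arm gap SSC and the longer LSC, and reports the four junction
coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp
from .genome import GenomeRecord


class NoInvertedRepeatError(ValueError):
    """No inverted repeat of at least ``min_ir`` bp was found."""


@dataclass
class Quadripartite:
    """The four intervals (1-based inclusive) and junction coordinates.

    Junctions are reported as the coordinate of the last base of the upstream
    region: ``junctions = (LSC/IRb, IRb/SSC, SSC/IRa, IRa/LSC)``.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    junctions: tuple[int, int, int, int]
    ir_identity: float
    genome_length: int
    lsc_wraps: bool = False

    def _len(self, iv: tuple[int, int], wraps: bool = False) -> int:
        s, e = iv
        if wraps:
            return (self.genome_length - s + 1) + e
        return e - s + 1

    @property
    def ir_length(self) -> int:
        return self._len(self.irb)

    @property
    def lsc_length(self) -> int:
        return self._len(self.lsc, self.lsc_wraps)

    @property
    def ssc_length(self) -> int:
        return self._len(self.ssc)

    def tiles_genome(self) -> bool:
        return (
            self.lsc_length + self.ssc_length + 2 * self.ir_length
            == self.genome_length
        )


@dataclass
class JunctionGene:
    junction: str  # LSC/IRb, IRb/SSC, SSC/IRa, IRa/LSC
    coordinate: int
    gene: str | None
    crosses: bool
    extension_into_ir: int  # nt of the gene inside the IR (0 if none crosses)
    distance: int  # 0 if crossing, else distance to the nearest gene


@dataclass
class JunctionReport:
    entries: list[JunctionGene]

    def by_junction(self, name: str) -> JunctionGene:
        for e in self.entries:
            if e.junction == name:
                return e
        raise KeyError(name)


# ---------------------------------------------------------------------------


def _longest_inverted_pair(seq: str, min_ir: int):
    """Longest pair (i, j, L): seq[i:i+L] == revcomp(seq[j:j+L]), disjoint, i < j.

    Block anchoring: any exact common substring of seq and its reverse
    complement with length >= min_ir contains one of the k-blocks of seq
    (k = min_ir // 2) aligned at a multiple-of-k boundary, so every candidate
    is found by locating each block in the reverse complement and extending
    the match maximally in both directions.
    """
    n = len(seq)
    rc = revcomp(seq)
    k = max(8, min_ir // 2)
    found: set[tuple[int, int, int]] = set()
    for m in range(0, n - k + 1, k):
        block = seq[m : m + k]
        q = rc.find(block)
        while q != -1:
            p, qq, L = m, q, k
            while p > 0 and qq > 0 and seq[p - 1] == rc[qq - 1]:
                p -= 1
                qq -= 1
                L += 1
            while p + L < n and qq + L < n and seq[p + L] == rc[qq + L]:
                L += 1
            # map the rc window back to genome coordinates
            i, j = p, n - qq - L
            if j < i:
                i, j = j, i
            if L >= min_ir and j >= i + L:  # disjoint arms only
                found.add((i, j, L))
            q = rc.find(block, q + 1)
    if not found:
        raise NoInvertedRepeatError(
            f"no inverted repeat of >= {min_ir} bp found (n={n})"
        )
    # longest first; ties broken toward the lower coordinate for determinism
    return sorted(found, key=lambda t: (-t[2], t[0], t[1]))[0]


_CMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def detect_quadripartite(
    seq: str | GenomeRecord, min_ir: int = 10_000, ir_identity: float = 1.0
) -> Quadripartite:
    """Find the IR/LSC/SSC architecture of a plastome sequence.

    ``ir_identity`` < 1 enables Hamming-tolerant outward extension of the
    exact maximal core (for degraded genomes); the default demands identical
    arms, which matches deposited plastome annotations.
    """
    if isinstance(seq, GenomeRecord):
        seq = seq.seq
    seq = seq.upper()
    n = len(seq)
    if n <= 2 * min_ir:
        raise ValueError("sequence shorter than twice min_ir")
    i, j, L = _longest_inverted_pair(seq, min_ir)
    # maximal outward extension of the exact core
    while i > 0 and j + L < n and _CMP.get(seq[i - 1]) == seq[j + L]:
        i -= 1
        L += 1
    while i + L < j and _CMP.get(seq[i + L]) == seq[j - 1]:
        j -= 1
        L += 1
    identity = 1.0
    if ir_identity < 1.0:
        i, j, L, identity = _extend_tolerant(seq, i, j, L, ir_identity)

    arm1 = (i + 1, i + L)  # 1-based inclusive
    arm2 = (j + 1, j + L)
    mid = (i + L + 1, j)  # between the arms; empty if j == i + L
    mid_len = j - (i + L)
    out_len = n - L - j + i  # before arm1 plus after arm2 (circular)
    if mid_len <= 0 or out_len <= 0:
        raise NoInvertedRepeatError("inverted repeat arms leave no single-copy gap")
    lsc_wraps = False
    if mid_len < out_len:
        ssc = mid
        irb, ira = arm1, arm2
        if i == 0:
            lsc = (j + L + 1, n)
        elif j + L == n:
            lsc = (1, i)
        else:
            lsc = (j + L + 1, i)  # wraps the origin
            lsc_wraps = True
    else:
        ssc_wraps = not (i == 0 or j + L == n)
        if ssc_wraps:
            raise NoInvertedRepeatError(
                "SSC spans the origin; rotate the genome to a standard origin first"
            )
        ssc = (j + L + 1, n) if i == 0 else (1, i)
        irb, ira = (arm2, arm1) if i == 0 else (arm1, arm2)
        lsc = mid
    junctions = (lsc[1] if not lsc_wraps else lsc[1], irb[1], ssc[1], ira[1])
    quad = Quadripartite(
        lsc=lsc,
        irb=irb,
        ssc=ssc,
        ira=ira,
        junctions=junctions,
        ir_identity=identity,
        genome_length=n,
        lsc_wraps=lsc_wraps,
    )
    assert quad.tiles_genome(), "quadripartite intervals must tile the genome"
    return quad


def _extend_tolerant(seq: str, i: int, j: int, L: int, min_identity: float):
    """Greedy outward extension allowing mismatches while identity stays >= cutoff."""
    n = len(seq)
    mism = 0
    bi, bj, bL, bm = i, j, L, 0
    while i > 0 and j + L < n and i + L < j:
        i -= 1
        L += 1
        if _CMP.get(seq[i]) != seq[j + L - 1]:
            mism += 1
        if (L - mism) / L >= min_identity:
            bi, bj, bL, bm = i, j, L, mism
    identity = (bL - bm) / bL if bL else 1.0
    return bi, bj, bL, identity


# ---------------------------------------------------------------------------


def junction_report(quad: Quadripartite, record: GenomeRecord) -> JunctionReport:
    """For each junction, the gene crossing it (with its overhang into the IR),
    or the nearest gene and its distance when none crosses."""
    names = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")
    ir_ivs = [quad.irb, quad.ira]
    n = quad.genome_length
    genes = record.genes() or record.coding_features()
    entries = []
    for name, coord in zip(names, quad.junctions):
        nxt = coord % n + 1  # first base of the downstream region
        crossing = None
        if nxt > coord:  # a junction at the genome end only wraps for
            for g in genes:  # origin-spanning features, handled as nearest
                if g.start <= coord and g.end >= nxt:
                    crossing = g
                    break
        if crossing is not None:
            ext = 0
            for a, b in ir_ivs:
                lo, hi = max(crossing.start, a), min(crossing.end, b)
                if lo <= hi:
                    ext = max(ext, hi - lo + 1)
            entries.append(JunctionGene(name, coord, crossing.name, True, ext, 0))
        else:
            best, dist = None, n
            for g in genes:
                d = min(abs(g.start - coord), abs(g.end - coord))
                d = min(d, n - d)  # circular distance
                if d < dist:
                    best, dist = g, d
            entries.append(
                JunctionGene(name, coord, best.name if best else None, False, 0, dist)
            )
    return JunctionReport(entries)
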