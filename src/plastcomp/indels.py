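"""Exon indel extraction/coding and detection of small palindrome-flanked
inversions.

Indels are coded with simple indel coding: every maximal gap run with
identical boundaries is one binary character, polarized against an outgroup
row ('-' in the outgroup means the gap is ancestral, so taxa WITH sequence
carry an insertion).  Small inversions are recognized by their hallmark: a
segment between the arms of a palindromic repeat whose reverse complement,
but not the segment itself, matches the reference.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

try:  # edit-distance identity for length-divergent segments
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from ._seq import encode, revcomp
from .divergence import GAP, AlignedSet, _gap_runs
from .parsimony import CharacterMatrix, Topology, map_character
from .repeats import RepeatMotif, find_palindromic


@dataclass
class IndelEvent:
    gene: str
    position: int  # 1-based aligned column of the gap run start
    size: int
    polarity: str  # '+' insertion / '-' deletion (relative to the outgroup)
    derived_taxa: tuple
    classification: str | None = None
    origins: int | None = None

    @property
    def character_id(self) -> str:
        return f"{self.gene}:{self.position}:{self.size}{self.polarity}"


@dataclass
class InversionEvent:
    location: str  # flanking feature description or region name
    segment: tuple[int, int]  # reference coordinates, 1-based inclusive
    arms: tuple  # ((start, end), (start, end)) of the flanking arms
    taxa: tuple  # taxa carrying the inverted orientation
    inverted_identity: float
    direct_identity: float


# ---------------------------------------------------------------------------
# indels


def extract_exon_indels(
    gene_alignments: dict[str, AlignedSet], outgroup: str
) -> list[IndelEvent]:
    """Candidate informative indel events from per-gene exon alignments.

    Each maximal gap run with identical boundaries shared by a set of taxa is
    a candidate; events are kept when the derived state is present in at least
    one and absent in at least one ingroup taxon (autapomorphies retained).
    """
    events = []
    for gene, aln in gene_alignments.items():
        if outgroup not in aln.taxa:
            raise ValueError(f"outgroup {outgroup!r} missing from {gene} alignment")
        ingroup = [t for t in aln.taxa if t != outgroup]
        runs: dict = {}
        for t in aln.taxa:
            for run in _gap_runs(aln.data[aln.taxa.index(t)]):
                runs.setdefault(run, set()).add(t)
        for (s, e), bearers in sorted(runs.items()):
            gapped_in = [t for t in ingroup if t in bearers]
            if outgroup in bearers:
                polarity = "+"  # gap ancestral: sequence present = insertion
                derived = tuple(t for t in ingroup if t not in bearers)
            else:
                polarity = "-"  # gap derived: a deletion
                derived = tuple(gapped_in)
            if not derived or len(derived) == len(ingroup):
                continue  # not variable among the ingroup
            events.append(
                IndelEvent(
                    gene=gene,
                    position=s + 1,
                    size=e - s + 1,
                    polarity=polarity,
                    derived_taxa=derived,
                )
            )
    return events


def code_and_append(events: list[IndelEvent], M: CharacterMatrix) -> CharacterMatrix:
    """Append one binary character per indel event (derived state = 1)."""
    if not events:
        return M
    cols = {t: "" for t in M.taxa}
    for ev in events:
        for t in M.taxa:
            cols[t] += "1" if t in ev.derived_taxa else "0"
    return M.append_characters(cols, labels=[ev.character_id for ev in events])


def classify_events(
    events: list[IndelEvent], t: Topology, outgroup: str
) -> list[IndelEvent]:
    """Parsimony-map each event on a reference topology (synapomorphy iff the
    derived state arises once)."""
    out = []
    for ev in events:
        states = {
            tx: ("1" if tx in ev.derived_taxa else "0") for tx in t.taxa
        }
        states[outgroup] = "0"
        fate = map_character(t, states, outgroup, character=ev.character_id)
        out.append(
            replace(ev, classification=fate.classification, origins=fate.origins)
        )
    return out


# ---------------------------------------------------------------------------
# small inversions


def _segment_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        ca, cb = encode(a), encode(b)
        return float(((ca == cb) & (ca < 4)).sum()) / len(a)
    if _HAVE_EDLIB:
        d = edlib.align(a, b)["editDistance"]
        return 1.0 - d / max(len(a), len(b))
    return 0.0


def detect_small_inversions(
    aln: AlignedSet,
    reference: str,
    motifs: list[RepeatMotif] | None = None,
    min_arm: int = 15,
    max_gap: int = 200,
    min_identity: float = 0.90,
    inverted_threshold: float = 0.90,
    direct_threshold: float = 0.50,
    location: str = "",
) -> list[InversionEvent]:
    """Find segments carried in opposite orientation by some taxa.

    Candidate segments are anchored by palindromic arm pairs on the ungapped
    reference (or supplied motifs).  A taxon carries the inverted orientation
    when the reverse complement of its segment matches the reference segment
    at >= ``inverted_threshold`` while the direct comparison stays below
    ``direct_threshold``.
    """
    ridx = aln.taxa.index(reference)
    refrow = aln.data[ridx]
    ref_cols = np.nonzero(refrow != GAP)[0]
    refseq = refrow[refrow != GAP].tobytes().decode()
    if motifs is None:
        motifs = find_palindromic(
            refseq, min_arm=min_arm, max_gap=max_gap, min_identity=min_identity
        )
    events = []
    for m in motifs:
        (a1s, a1e, _), (a2s, a2e, _) = sorted(m.copies)[:2]
        seg_lo, seg_hi = a1e + 1, a2s - 1  # reference coords, 1-based
        if seg_hi < seg_lo:
            continue
        cols = ref_cols[seg_lo - 1 : seg_hi]
        lo, hi = int(cols[0]), int(cols[-1]) + 1
        ref_seg = refseq[seg_lo - 1 : seg_hi]
        inverted = []
        inv_id = dir_id = None
        for ti, taxon in enumerate(aln.taxa):
            if taxon == reference:
                continue
            row = aln.data[ti, lo:hi]
            seg = row[row != GAP].tobytes().decode()
            if not seg:
                continue
            direct = _segment_identity(seg, ref_seg)
            inv = _segment_identity(revcomp(seg), ref_seg)
            if inv >= inverted_threshold and direct < direct_threshold:
                inverted.append(taxon)
                inv_id, dir_id = inv, direct
        if inverted:
            events.append(
                InversionEvent(
                    location=location or f"ref:{seg_lo}-{seg_hi}",
                    segment=(seg_lo, seg_hi),
                    arms=((a1s, a1e), (a2s, a2e)),
                    taxa=tuple(inverted),
                    inverted_identity=float(inv_id),
                    direct_identity=float(dir_id),
                )
            )
    # an inverted segment spawns nested arm pairs; keep the outermost call
    # per overlapping segment/taxon-set group
    events.sort(key=lambda e: (e.segment[0] - e.segment[1], e.segment[0]))
    kept: list[InversionEvent] = []
    for ev in events:
        if any(
            ev.segment[0] <= k.segment[1]
            and ev.segment[1] >= k.segment[0]
            and set(ev.taxa) == set(k.taxa)
            for k in kept
        ):
            continue
        kept.append(ev)
    return sorted(kept, key=lambda e: e.segment)


def normalize_inversions(
    aln: AlignedSet,
    events: list[InversionEvent],
    mode: str = "exclude",
    reference: str | None = None,
) -> AlignedSet:
    """Remove or reorient detected inversions before downstream analysis.

    exclude: drop the inversion columns.  reorient: reverse-complement the
    segment in the rows carrying the minority orientation (idempotent:
    re-detection finds nothing afterwards).  Overlapping events are processed
    outermost-first.
    """
    if mode not in ("exclude", "reorient"):
        raise ValueError("mode must be 'exclude' or 'reorient'")
    reference = reference or aln.taxa[0]
    ridx = aln.taxa.index(reference)
    ref_cols = np.nonzero(aln.data[ridx] != GAP)[0]
    data = aln.data.copy()
    spans = []
    for ev in sorted(events, key=lambda e: e.segment[1] - e.segment[0], reverse=True):
        cols = ref_cols[ev.segment[0] - 1 : ev.segment[1]]
        if len(cols) == 0:
            continue
        spans.append((int(cols[0]), int(cols[-1]) + 1, ev))
    if mode == "exclude":
        drop = np.zeros(aln.length, dtype=bool)
        for lo, hi, _ in spans:
            drop[lo:hi] = True
        return AlignedSet(list(aln.taxa), data[:, ~drop])
    comp = np.arange(256, dtype=np.uint8)
    for x, y in zip(b"ACGTacgt", b"TGCAtgca"):
        comp[x] = y
    for lo, hi, ev in spans:
        for taxon in ev.taxa:
            ti = aln.taxa.index(taxon)
            data[ti, lo:hi] = comp[data[ti, lo:hi]][::-1]
    return AlignedSet(list(aln.taxa), data)
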