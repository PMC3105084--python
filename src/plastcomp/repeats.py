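"""Repeat detection, merging, classification and cross-genome comparison.

Three repeat classes are scanned with the study-standard thresholds: dispersed
(same-strand copies >= 30 bp), tandem (adjacent copies, unit >= 15 bp) and
palindromic (reverse-complement arm pairs >= 20 bp with a gap <= 3 kb), all at
>= 90% ungapped identity.  A fourth class, "similarity", collects motifs whose
copies merely reflect related loci (two tRNA copies, or duplicated gene pairs
such as psaA/psaB); these are excluded from the phylogenetic repeat matrix.

When scanning a whole plastome, one inverted-repeat arm is masked first so the
genome-scale IR does not flood the repeat list.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._matchengine import PairMatch, palindromic_pairs, scan_pairs, _identity_fraction
from ._seq import encode
from .genome import GenomeRecord, coding_intervals
from .parsimony import CharacterMatrix

DEFAULT_MIN_DISPERSED = 30
DEFAULT_MIN_TANDEM = 15
DEFAULT_MIN_PALINDROMIC = 20
DEFAULT_MAX_GAP = 3000
DEFAULT_IDENTITY = 0.90

#: gene pairs whose mutual similarity generates spurious repeat calls
DUPLICATE_GENE_PAIRS = [frozenset({"psaA", "psaB"})]


@dataclass(frozen=True)
class RepeatMotif:
    type: str  # dispersed | tandem | palindromic | similarity
    copies: tuple  # ((start, end, strand), ...) 1-based inclusive
    unit_length: int
    identity: float
    genome_id: str = ""
    location_class: str = ""  # coding | noncoding | both
    context: tuple = ()  # per-copy overlapping/nearest feature names

    @property
    def interval(self) -> tuple[int, int]:
        return min(s for s, _, _ in self.copies), max(e for _, e, _ in self.copies)


@dataclass
class RepeatSet:
    genome_id: str
    motifs: list[RepeatMotif]

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)

    def of_type(self, t: str) -> list[RepeatMotif]:
        return [m for m in self.motifs if m.type == t]

    def non_similarity(self) -> list[RepeatMotif]:
        return [m for m in self.motifs if m.type != "similarity"]


@dataclass
class SharedRepeatTable:
    """Counts of repeat characters per taxon subset, plus unique counts."""

    shared: dict  # frozenset(taxa) -> count (subsets with >= 2 taxa)
    unique: dict  # taxon -> count of repeats private to it

    def shared_by(self, taxa) -> int:
        return self.shared.get(frozenset(taxa), 0)


# ---------------------------------------------------------------------------
# finders


def find_dispersed(
    seq: str,
    min_len: int = DEFAULT_MIN_DISPERSED,
    min_identity: float = DEFAULT_IDENTITY,
    max_len: int = 1000,
) -> list[RepeatMotif]:
    """Maximal same-strand repeat pairs (ungapped identity model)."""
    out = []
    for m in scan_pairs(seq, None, min_len=min_len, min_identity=min_identity, max_len=max_len):
        out.append(
            RepeatMotif(
                type="dispersed",
                copies=((m.p + 1, m.p + m.length, 1), (m.q + 1, m.q + m.length, 1)),
                unit_length=m.length,
                identity=m.identity,
            )
        )
    return out


def find_palindromic(
    seq: str,
    min_arm: int = DEFAULT_MIN_PALINDROMIC,
    max_gap: int = DEFAULT_MAX_GAP,
    min_identity: float = DEFAULT_IDENTITY,
    max_len: int = 1000,
) -> list[RepeatMotif]:
    """Arm pairs where one arm matches the reverse complement of the other.

    The genome-scale IR does not appear here: its inter-arm gap (the SSC)
    exceeds ``max_gap``, and whole-genome scans additionally mask one arm.
    """
    out = []
    for m in palindromic_pairs(seq, min_arm=min_arm, max_gap=max_gap,
                               min_identity=min_identity, max_len=max_len):
        out.append(
            RepeatMotif(
                type="palindromic",
                copies=((m.p + 1, m.p + m.length, 1), (m.q + 1, m.q + m.length, -1)),
                unit_length=m.length,
                identity=m.identity,
            )
        )
    return out


def _consensus(copies: list[str]) -> str:
    cols = []
    for i in range(len(copies[0])):
        col = [c[i] for c in copies]
        cols.append(max(sorted(set(col)), key=col.count))
    return "".join(cols)


def _copy_identity(a: str, b: str) -> float:
    ca, cb = encode(a), encode(b)
    return float(((ca == cb) & (ca < 4)).sum()) / len(a)


def find_tandem(
    seq: str,
    min_unit: int = DEFAULT_MIN_TANDEM,
    min_identity: float = DEFAULT_IDENTITY,
    max_unit: int = 100,
) -> list[RepeatMotif]:
    """Runs of >= 2 adjacent copies of a unit >= min_unit.

    Candidates come from the adjacent-copy identity predicate; arrays with
    more than two copies are validated against the column-majority consensus
    (each copy must match the consensus at >= min_identity), trimming failing
    copies from the right.  Redundant motifs contained in a kept motif's
    interval are dropped (longest span first, then smallest unit).
    """
    n = len(seq)
    codes = encode(seq)
    ident = _identity_fraction(min_identity)
    need = lambda u: -(-ident.numerator * u // ident.denominator)  # ceil(id*u)
    cands = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        eq = (codes[u:] == codes[:-u]) & (codes[u:] < 4)
        if len(eq) < u:
            continue
        cs = np.concatenate([[0], np.cumsum(eq)])
        match_u = cs[u:] - cs[:-u]  # matches between copy at i and copy at i+u
        P = match_u >= need(u)  # predicate over starts 0 .. n-2u
        for i in np.nonzero(P)[0]:
            if i >= u and P[i - u]:
                continue  # not a chain start
            c = 2
            while i + c * u <= n - u and P[i + (c - 1) * u]:
                c += 1
            cands.append((int(i), u, c))
    motifs = []
    for i, u, c in cands:
        copies = [seq[i + t * u : i + (t + 1) * u] for t in range(c)]
        while len(copies) > 2:
            cons = _consensus(copies)
            bad = [t for t, cp in enumerate(copies) if _copy_identity(cp, cons) < float(ident)]
            if not bad:
                break
            copies = copies[:-1]
        c = len(copies)
        cons = _consensus(copies) if c > 2 else copies[0]
        idents = [_copy_identity(cp, cons) for cp in copies[(0 if c > 2 else 1):]]
        motifs.append(
            RepeatMotif(
                type="tandem",
                copies=tuple((i + t * u + 1, i + (t + 1) * u, 1) for t in range(c)),
                unit_length=u,
                identity=min(idents),
            )
        )
    # redundancy: keep longest spans, preferring the smallest unit
    motifs.sort(key=lambda m: (-(m.interval[1] - m.interval[0]), m.unit_length, m.interval[0]))
    kept: list[RepeatMotif] = []
    for m in motifs:
        s, e = m.interval
        if any(k.interval[0] <= s and k.interval[1] >= e for k in kept):
            continue
        kept.append(m)
    return sorted(kept, key=lambda m: m.interval)


# ---------------------------------------------------------------------------
# genome-level resolution


def _overlapping_features(record: GenomeRecord, start: int, end: int) -> list[str]:
    hits = []
    for f in record.genes() or record.coding_features():
        if f.start <= end and f.end >= start:
            hits.append(f.name)
    return hits


def _nearest_feature(record: GenomeRecord, start: int, end: int) -> str | None:
    best, dist = None, None
    for f in record.genes() or record.coding_features():
        d = max(f.start - end, start - f.end, 0)
        if dist is None or d < dist:
            best, dist = f.name, d
    return best


def _copy_context(record: GenomeRecord, start: int, end: int) -> tuple:
    """Overlapping gene names, or the nearest gene when none overlaps.

    Overlap and proximity are deliberately not distinguished: a copy sitting
    1 bp outside a gene in one genome and 1 bp inside it in another must still
    land in the same homologous-region context."""
    hits = _overlapping_features(record, start, end)
    if hits:
        return tuple(sorted(set(hits)))
    near = _nearest_feature(record, start, end)
    return (near,) if near else ()


def _merge_same_type(motifs: list[RepeatMotif]) -> list[RepeatMotif]:
    """Union-merge motifs of one type whose copy intervals overlap."""
    parent = list(range(len(motifs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(motifs)):
        for j in range(i + 1, len(motifs)):
            if any(
                s1 <= e2 and e1 >= s2
                for s1, e1, _ in motifs[i].copies
                for s2, e2, _ in motifs[j].copies
            ):
                parent[find(j)] = find(i)
    groups: dict[int, list[RepeatMotif]] = {}
    for i, m in enumerate(motifs):
        groups.setdefault(find(i), []).append(m)
    out = []
    for ms in groups.values():
        copies = []
        for m in ms:
            for c in m.copies:
                if not any(c[0] <= e and c[1] >= s for s, e, _ in copies):
                    copies.append(c)
        rep = max(ms, key=lambda m: m.unit_length)
        out.append(replace(rep, copies=tuple(sorted(copies))))
    return sorted(out, key=lambda m: m.interval)


def resolve_and_classify(
    dispersed: list[RepeatMotif],
    tandem: list[RepeatMotif],
    palindromic: list[RepeatMotif],
    record: GenomeRecord,
    duplicate_gene_pairs=None,
) -> RepeatSet:
    """Merge overlapping motifs, apply type priority and annotate.

    A genomic region carries one repeat type only, tandem taking priority over
    dispersed.  Motifs whose copies overlap two tRNA genes or both members of
    a known duplicated gene pair are reclassified as "similarity".  Location
    class is coding/noncoding with "both" for class-spanning motifs.
    """
    for group in (dispersed, tandem, palindromic):
        for m in group:
            if m.genome_id and m.genome_id != record.id:
                raise ValueError("motifs from different genomes cannot be combined")
    duplicate_gene_pairs = duplicate_gene_pairs or DUPLICATE_GENE_PAIRS
    tandem = _merge_same_type(tandem)
    dispersed = _merge_same_type(dispersed)
    palindromic = _merge_same_type(palindromic)
    # tandem regions win over dispersed
    tandem_ivs = [m.interval for m in tandem]
    kept_disp = []
    for m in dispersed:
        copies = [
            c
            for c in m.copies
            if not any(c[0] <= e and c[1] >= s for s, e in tandem_ivs)
        ]
        if len(copies) >= 2:
            kept_disp.append(replace(m, copies=tuple(copies)))
    coding = coding_intervals(record)
    trnas = [f for f in record.features if f.kind == "tRNA"]

    def annotate(m: RepeatMotif) -> RepeatMotif:
        ctx = tuple(_copy_context(record, s, e) for s, e, _ in m.copies)
        in_coding = [
            any(s <= ce and e >= cs for cs, ce in coding) for s, e, _ in m.copies
        ]
        loc = "both" if any(in_coding) and not all(in_coding) else (
            "coding" if all(in_coding) else "noncoding"
        )
        mtype = m.type
        trna_hits = set()
        for s, e, _ in m.copies:
            for f in trnas:
                if f.start <= e and f.end >= s:
                    trna_hits.add((f.name, f.start))
        if len(trna_hits) >= 2:
            mtype = "similarity"
        else:
            gene_hits = {g for c in ctx for g in c if not g.startswith("near:")}
            for pair in duplicate_gene_pairs:
                if pair <= gene_hits:
                    mtype = "similarity"
                    break
        return replace(m, genome_id=record.id, location_class=loc, context=ctx, type=mtype)

    motifs = [annotate(m) for m in tandem + kept_disp + palindromic]
    return RepeatSet(record.id, sorted(motifs, key=lambda m: m.interval))


def scan_genome(
    record: GenomeRecord,
    quadripartite=None,
    min_dispersed: int = DEFAULT_MIN_DISPERSED,
    min_tandem: int = DEFAULT_MIN_TANDEM,
    min_palindromic: int = DEFAULT_MIN_PALINDROMIC,
    max_gap: int = DEFAULT_MAX_GAP,
    min_identity: float = DEFAULT_IDENTITY,
) -> RepeatSet:
    """Full repeat scan of one genome with one IR arm masked."""
    seq = record.seq
    if quadripartite is not None:
        s, e = quadripartite.ira
        seq = seq[: s - 1] + "N" * (e - s + 1) + seq[e:]
    disp = find_dispersed(seq, min_dispersed, min_identity)
    tand = find_tandem(seq, min_tandem, min_identity)
    pal = find_palindromic(seq, min_palindromic, max_gap, min_identity)
    return resolve_and_classify(disp, tand, pal, record)


# ---------------------------------------------------------------------------
# cross-genome comparison


def _character_key(m: RepeatMotif):
    """Two motifs in different genomes are the same character iff same type,
    identical unit length and identical annotation context (homologous region)."""
    return (m.type, m.unit_length, tuple(sorted(m.context)))


def shared_repeats(sets: list[RepeatSet]) -> SharedRepeatTable:
    if len(sets) < 2:
        raise ValueError("shared repeat analysis needs at least two genomes")
    presence: dict = {}
    for rs in sets:
        for m in rs.non_similarity():
            presence.setdefault(_character_key(m), set()).add(rs.genome_id)
    shared: dict = {}
    unique = {rs.genome_id: 0 for rs in sets}
    for key, taxa in presence.items():
        if len(taxa) == 1:
            unique[next(iter(taxa))] += 1
        else:
            fs = frozenset(taxa)
            shared[fs] = shared.get(fs, 0) + 1
    return SharedRepeatTable(shared=shared, unique=unique)


def to_binary_matrix(sets: list[RepeatSet]) -> CharacterMatrix:
    """Presence/absence matrix over distinct repeat characters.

    Similarity-type repeats are excluded; taxa order follows the input sets.
    """
    taxa = [rs.genome_id for rs in sets]
    presence: dict = {}
    for rs in sets:
        for m in rs.non_similarity():
            presence.setdefault(_character_key(m), set()).add(rs.genome_id)
    keys = sorted(presence, key=repr)
    rows = {
        t: "".join("1" if t in presence[k] else "0" for k in keys) for t in taxa
    }
    return CharacterMatrix(
        taxa=taxa,
        rows=[rows[t] for t in taxa],
        kind="standard",
        labels=[repr(k) for k in keys],
    )
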