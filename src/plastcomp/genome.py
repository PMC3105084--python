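"""Plastome records: GenBank/FASTA I/O, genome statistics and region partitioning.

Coordinates are 1-based inclusive on the public surface (GenBank convention)
and 0-based half-open internally; conversion happens at the boundaries of the
functions in this module.  Circular genomes are treated linearly in their
deposited rotation; an optional :func:`rotate` utility re-origins a record.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

log = logging.getLogger(__name__)

GENE_KINDS = ("gene", "CDS", "tRNA", "rRNA")
#: feature kinds whose exons count as coding sequence
CODING_KINDS = ("CDS", "tRNA", "rRNA")


@dataclass
class Feature:
    """An annotated locus: one or more (start, end, strand) intervals, 1-based inclusive."""

    kind: str
    name: str
    intervals: list[tuple[int, int, int]]  # (start, end, strand); strand in {+1, -1}
    is_duplicated: bool = False
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        for s, e, strand in self.intervals:
            if s > e and not self.wraps_origin:
                raise ValueError(f"feature {self.name}: start {s} > end {e}")
            if strand not in (1, -1):
                raise ValueError(f"feature {self.name}: strand must be +1/-1")

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.intervals)

    def span_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.intervals)


@dataclass
class GenomeRecord:
    """One plastome: identifier, (circular) nucleotide sequence and features."""

    id: str
    seq: str
    taxon: str = ""
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        self.seq = self.seq.upper()
        n = len(self.seq)
        for f in self.features:
            if f.start < 1 or f.end > n:
                raise ValueError(f"feature {f.name} outside [1, {n}]")

    def __len__(self) -> int:
        return len(self.seq)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def coding_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind in ("CDS", "tRNA", "rRNA")]


@dataclass(frozen=True)
class Region:
    name: str
    cls: str  # "coding" | "noncoding"
    start: int  # 1-based inclusive
    end: int
    genome_id: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    regions: list[Region]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def of_class(self, cls: str) -> list[Region]:
        return [r for r in self.regions if r.cls == cls]


# ---------------------------------------------------------------------------
# I/O


def read_genbank(path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    join(...) locations become multi-interval features; unparseable features
    are skipped with a logged warning.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: record has no usable sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    feats: list[Feature] = []
    for f in rec.features:
        if f.type not in GENE_KINDS:
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", [None])[0]
            or f.qualifiers.get("product", ["?"])[0]
        )
        try:
            parts = f.location.parts
            intervals = [
                (int(p.start) + 1, int(p.end), int(p.strand or 1)) for p in parts
            ]
            intervals.sort()
        except Exception as exc:  # malformed location
            log.warning("skipping feature %s in %s: %s", name, path, exc)
            continue
        feats.append(Feature(kind=f.type, name=name, intervals=intervals))
    organism = rec.annotations.get("organism", "")
    return GenomeRecord(id=rec.id, seq=seq, taxon=organism, circular=circular, features=feats)


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a record back out as a GenBank flat file (round-trips coordinates)."""
    sr = SeqRecord(Seq(record.seq), id=record.id, name=record.id[:16], description="")
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    if record.taxon:
        sr.annotations["organism"] = record.taxon
    for f in record.features:
        locs = [SimpleLocation(s - 1, e, strand) for s, e, strand in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        sr.features.append(SeqFeature(loc, type=f.kind, qualifiers={"gene": [f.name]}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write([sr], str(path), "genbank")


def read_fasta(path) -> list[GenomeRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(GenomeRecord(id=rec.id, seq=str(rec.seq), taxon=rec.description))
    return out


def write_fasta(records, path) -> None:
    records = [records] if isinstance(records, GenomeRecord) else list(records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), 70):
                fh.write(r.seq[i : i + 70] + "\n")


def rotate(record: GenomeRecord, new_origin: int) -> GenomeRecord:
    """Re-origin a circular record so base ``new_origin`` (1-based) becomes base 1.

    Features spanning the new origin are split into two intervals and flagged.
    """
    n = len(record)
    shift = new_origin - 1
    seq = record.seq[shift:] + record.seq[:shift]
    feats = []
    for f in record.features:
        ivs, wraps = [], False
        for s, e, strand in f.intervals:
            s0, e0 = (s - 1 - shift) % n, (e - 1 - shift) % n
            if s0 <= e0:
                ivs.append((s0 + 1, e0 + 1, strand))
            else:  # split at origin
                wraps = True
                ivs.append((s0 + 1, n, strand))
                ivs.append((1, e0 + 1, strand))
        feats.append(replace(f, intervals=sorted(ivs), wraps_origin=wraps))
    return GenomeRecord(record.id, seq, record.taxon, record.circular, feats)


# ---------------------------------------------------------------------------
# statistics


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def coding_intervals(record: GenomeRecord) -> list[tuple[int, int]]:
    """Merged union of all CDS/tRNA/rRNA exon intervals (1-based inclusive)."""
    ivs = [(s, e) for f in record.coding_features() for s, e, _ in f.intervals]
    return _merge_intervals(ivs)


def genome_stats(record: GenomeRecord, quadripartite=None) -> dict:
    """Table-style genome summary.

    GC% is 100*(G+C)/length rounded to one decimal (ambiguity codes other
    than G/C count as non-GC).  Coding% is the union coverage of CDS/tRNA/rRNA
    exons, so overlapping annotations are not double counted.  A gene is
    "duplicated" when two gene features share a name; when the quadripartite
    structure is supplied, both copies must additionally lie wholly inside the
    two IR arms.
    """
    n = len(record)
    gc = 100.0 * (record.seq.count("G") + record.seq.count("C")) / n
    merged = coding_intervals(record)
    coding = sum(e - s + 1 for s, e in merged)
    if coding > n:
        raise AssertionError("coding coverage exceeds genome length")

    genes = record.genes()
    by_name: dict[str, list[Feature]] = {}
    for g in genes:
        by_name.setdefault(g.name, []).append(g)

    def _in_ir(f: Feature) -> bool:
        if quadripartite is None:
            return True
        return any(
            s >= a and e <= b
            for a, b in (quadripartite.irb, quadripartite.ira)
            for s, e, _ in f.intervals
        )

    duplicated = {
        name
        for name, fs in by_name.items()
        if len(fs) >= 2 and all(_in_ir(f) for f in fs)
    }
    cds_names = {f.name for f in record.features if f.kind == "CDS"}
    rna_names = {f.name for f in record.features if f.kind in ("tRNA", "rRNA")}
    n_protein = sum(1 for g in genes if g.name in cds_names)
    n_rna = sum(1 for g in genes if g.name in rna_names and g.name not in cds_names)
    return {
        "length_bp": n,
        "gc_percent": round(gc, 1),
        "coding_percent": round(100.0 * coding / n, 1),
        "n_genes": len(genes),
        "n_protein_coding": n_protein,
        "n_structural_rna": n_rna,
        "n_unique_genes": len(by_name) if genes else 0,
        "n_duplicated_genes": len(duplicated),
    }


# ---------------------------------------------------------------------------
# region partitioning


def partition_regions(
    record: GenomeRecord,
    min_len: int = 1,
    single_copy_only: bool = False,
    quadripartite=None,
) -> RegionSet:
    """Split the genome into coding exon regions and noncoding spacers/introns.

    Every coding exon segment and every intergenic spacer or intron of length
    >= ``min_len`` is emitted.  Spacers are named by their flanking genes
    ("trnD(GUC)-psbM"), introns as "<gene> intron".  With
    ``single_copy_only=True`` (requires ``quadripartite``) regions overlapping
    the IR arms are dropped.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(record)
    # attributed coding segments: (start, end, gene name)
    segs: list[tuple[int, int, str]] = []
    for f in record.coding_features():
        for s, e, _ in f.intervals:
            segs.append((s, e, f.name))
    segs.sort()
    # merge overlapping segments, keeping the name of the longest contributor
    merged: list[list] = []
    for s, e, name in segs:
        if merged and s <= merged[-1][1]:
            if e - s > merged[-1][1] - merged[-1][0]:
                merged[-1][2] = name
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e, name])

    regions: list[Region] = []
    for s, e, name in merged:
        regions.append(Region(name, "coding", s, e, record.id))
    for (s1, e1, n1), (s2, e2, n2) in zip(merged, merged[1:]):
        if s2 - e1 - 1 <= 0:
            continue
        name = f"{n1} intron" if n1 == n2 else f"{n1}-{n2}"
        regions.append(Region(name, "noncoding", e1 + 1, s2 - 1, record.id))
    if merged:  # leading / trailing noncoding stretches
        if merged[0][0] > 1:
            regions.append(Region(f"start-{merged[0][2]}", "noncoding", 1, merged[0][0] - 1, record.id))
        if merged[-1][1] < n:
            regions.append(Region(f"{merged[-1][2]}-end", "noncoding", merged[-1][1] + 1, n, record.id))

    regions = [r for r in regions if r.length >= min_len]
    if single_copy_only:
        if quadripartite is None:
            raise ValueError("single_copy_only requires a quadripartite structure")
        irs = (quadripartite.irb, quadripartite.ira)
        regions = [
            r
            for r in regions
            if not any(r.start <= b and r.end >= a for a, b in irs)
        ]
    return RegionSet(sorted(regions, key=lambda r: r.start))
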