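"""Synthetic quadripartite plastomes evolving on a known tree.

The generator builds a root genome with the canonical grass-plastome
architecture (LSC ~83 kb, SSC ~12.8 kb, two identical 21.8 kb IR arms; 131
gene features of which 112 names are unique and 19 are IR-duplicated; GC
~38.9%; ~50.6% coding) and evolves it along a user tree: substitutions (JC or
K2P) with region-specific rates, indels (geometric lengths, frame-preserving
in exons), repeat plants (dispersed/tandem/palindromic copies written into
spacers on chosen branches) and small inversions flipped between pre-planted
palindromic arms.  IR arms evolve concertedly: a substitution in one arm is
mirrored into the other, and indels are confined to single-copy regions, so
the arms stay identical and quadripartite detection stays exact.  Sites are
tracked by column identity, which yields an exact true alignment and a truth
log sufficient to replay every leaf genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from ._seq import revcomp
from .divergence import AlignedSet
from .genome import Feature, GenomeRecord, partition_regions
from .parsimony import CharacterMatrix, Topology

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP[_x] = _y

# region codes on the root coordinate system; PROTECTED sites take
# substitutions like noncoding sequence but no indels (planted inversion loci)
NONCODING, EXON, IR, FROZEN, PROTECTED = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class GeneSpec:
    name: str
    kind: str  # CDS | tRNA | rRNA
    length: int  # full span including introns
    strand: int = 1
    exons: tuple = ()  # exon lengths; empty = single exon of full length


@dataclass
class Architecture:
    lsc_len: int
    ssc_len: int
    ir_len: int
    lsc_genes: list
    ssc_genes: list
    ir_genes: list
    junction_overhang: int = 180  # ndhH extension into IRa
    gc: float = 0.389

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class RepeatPlant:
    """A repeat copy written into spacer sequence on one branch."""

    branch: str  # taxon label, internal node label, or "root"
    kind: str  # dispersed | tandem | palindromic
    unit: int
    region: str  # spacer name holding the (first) copy
    target_region: str | None = None  # dispersed: spacer receiving the second copy
    gap: int = 40  # palindromic arm gap
    copies: int = 2  # tandem copy count


@dataclass(frozen=True)
class InversionPlant:
    branch: str
    region: str  # spacer carrying the pre-planted arms
    arm: int = 22
    segment: int = 30


@dataclass
class SimulationConfig:
    tree: str  # newick with branch lengths (internal labels name branches)
    architecture: Architecture
    model: str = "JC"  # JC | K2P
    kappa: float = 2.0
    indel_rate: float = 0.08  # indel events per site per unit branch length
    indel_mean: float = 4.0  # geometric mean indel length (noncoding)
    exon_indel_weight: float = 0.1  # indels are much rarer inside exons
    coding_weight: float = 0.6
    noncoding_weight: float = 1.4
    ir_weight: float = 0.5
    region_multipliers: dict = field(default_factory=dict)
    repeat_plants: list = field(default_factory=list)
    inversion_plants: list = field(default_factory=list)
    seed: int | None = None


@dataclass
class BranchLog:
    branch: str
    length: float
    taxa_below: tuple
    substitutions: list = field(default_factory=list)  # (id, old, new) / mirrored too
    insertions: list = field(default_factory=list)  # (anchor_id, ids, bases)
    deletions: list = field(default_factory=list)  # (ids,)
    overwrites: list = field(default_factory=list)  # (ids, bases) repeat plants etc.
    repeat_plants: list = field(default_factory=list)
    inversions: list = field(default_factory=list)


@dataclass
class TruthLog:
    root_ids: list
    root_bases: str
    branches: list  # BranchLog in preorder
    region_names: list
    spacer_intervals: dict  # name -> (start, end) 1-based root coords

    def branch(self, name: str) -> BranchLog:
        for b in self.branches:
            if b.branch == name:
                return b
        raise KeyError(name)

    def replay(self) -> dict:
        """Re-apply every logged event from the root; returns taxon -> sequence.

        Parent/child relations are recovered from branch taxon sets (the
        parent of a branch is the smallest branch whose taxa strictly contain
        its own; otherwise the root)."""

        def apply(ids, bases, blog: BranchLog):
            ids = list(ids)
            bases = dict(bases)
            for cid, _old, new in blog.substitutions:
                bases[cid] = new
            for anchor, new_ids, nb in blog.insertions:
                at = ids.index(anchor) + 1 if anchor is not None else 0
                ids[at:at] = list(new_ids)
                for cid, x in zip(new_ids, nb):
                    bases[cid] = x
            for (dids,) in blog.deletions:
                dead = set(dids)
                ids = [i for i in ids if i not in dead]
                for cid in dids:
                    bases.pop(cid, None)
            for cids, newbases in blog.overwrites:
                for cid, nb in zip(cids, newbases):
                    bases[cid] = nb
            return ids, bases

        def parent_branch(b):
            cands = [
                o
                for o in self.branches
                if o is not b and set(b.taxa_below) > set() and
                set(b.taxa_below) < set(o.taxa_below)
            ]
            return min(cands, key=lambda o: len(o.taxa_below)) if cands else None

        root = (list(self.root_ids), dict(zip(self.root_ids, self.root_bases)))
        state_for: dict = {}
        for b in sorted(self.branches, key=lambda b: -len(b.taxa_below)):
            pb = parent_branch(b)
            base = state_for[pb.branch] if pb else root
            state_for[b.branch] = apply(base[0], base[1], b)
        out = {}
        for b in self.branches:
            if len(b.taxa_below) == 1:
                ids, bases = state_for[b.branch]
                out[b.taxa_below[0]] = "".join(bases[i] for i in ids)
        return out


@dataclass
class SimulationResult:
    config: SimulationConfig
    records: dict  # taxon -> GenomeRecord
    alignment: AlignedSet
    truth: TruthLog
    tree: Topology
    root_record: GenomeRecord
    quadripartite_truth: dict  # taxon -> dict of interval tuples (1-based)


# ---------------------------------------------------------------------------
# architectures


def _genes(defs):
    return [GeneSpec(*d) for d in defs]


def default_architecture(scale: float = 1.0, junction_overhang: int = 180) -> Architecture:
    """The published-anchor architecture, optionally scaled down.

    Scaling multiplies region and gene lengths but keeps the gene inventory
    (131 features, 112 unique names, 19 IR-duplicated), so every named spacer
    still exists at small scale.
    """
    t = lambda n: (n, "tRNA", 75)
    lsc = [
        ("psbA", "CDS", 1062), ("matK", "CDS", 1551), t("trnK(UUU)"),
        ("rps16", "CDS", 810, 1, (240, 228)), t("trnQ(UUG)"),
        ("psbK", "CDS", 186), ("psbI", "CDS", 111), t("trnS(GCA)"), t("trnR(UCU)"),
        t("trnG(UCC)"), t("trnT(GGU)"), t("trnE(UUC)"), t("trnY(GUA)"), t("trnD(GUC)"),
        ("psbM", "CDS", 105), ("petN", "CDS", 90), t("trnS(UGA)"), t("trnC(GCA)"),
        ("rpoB", "CDS", 3213), ("rpoC1", "CDS", 2052), ("rpoC2", "CDS", 4185),
        ("rps2", "CDS", 711), ("atpI", "CDS", 744), ("atpH", "CDS", 246),
        ("atpF", "CDS", 555, 1, (145, 410)), ("atpA", "CDS", 1524),
        ("psbD", "CDS", 1062), ("psbC", "CDS", 1386), ("psbZ", "CDS", 189),
        t("trnfM(CAU)"), ("rps14", "CDS", 303), ("psaB", "CDS", 2205),
        ("psaA", "CDS", 2253), ("ycf3", "CDS", 507, 1, (124, 230, 153)),
        t("trnS(GGA)"), ("rps4", "CDS", 606), t("trnT(UGU)"), t("trnL(UAA)"),
        t("trnF(GAA)"), ("ndhJ", "CDS", 477), ("ndhK", "CDS", 675),
        ("ndhC", "CDS", 363), t("trnV(UAC)"), t("trnM(CAU)"), ("atpE", "CDS", 408),
        ("atpB", "CDS", 1497), ("rbcL", "CDS", 1431), ("psaI", "CDS", 111),
        ("ycf4", "CDS", 555), ("cemA", "CDS", 690), ("petA", "CDS", 963),
        ("psbJ", "CDS", 123), ("psbL", "CDS", 117), ("psbF", "CDS", 120),
        ("psbE", "CDS", 252), ("petL", "CDS", 96), ("petG", "CDS", 114),
        t("trnW(CCA)"), t("trnP(UGG)"), t("trnP(GGG)"),
        ("psaJ", "CDS", 135), ("rpl33", "CDS", 201),
        ("rps18", "CDS", 306), ("rpl20", "CDS", 354), ("clpP", "CDS", 591),
        ("psbB", "CDS", 1527), ("psbT", "CDS", 108), ("psbN", "CDS", 132),
        ("psbH", "CDS", 222), ("petB", "CDS", 648), ("petD", "CDS", 483),
        ("rpoA", "CDS", 1014), ("rps11", "CDS", 417), ("rpl36", "CDS", 114),
        ("infA", "CDS", 324), ("rps8", "CDS", 399), ("rpl14", "CDS", 369),
        ("rpl16", "CDS", 1250, 1, (9, 399)), ("rps3", "CDS", 657),
        ("rpl22", "CDS", 462), t("trnH(GUG)"),
    ]
    ssc = [
        ("rps15", "CDS", 273), ("ndhF", "CDS", 2213), ("rpl32", "CDS", 174),
        t("trnL(UAG)"), ("ccsA", "CDS", 960), ("ndhD", "CDS", 1503),
        ("psaC", "CDS", 246), ("ndhE", "CDS", 306), ("ndhG", "CDS", 531),
        ("ndhI", "CDS", 504), ("ndhA", "CDS", 2100, 1, (553, 539)),
        ("ndhH", "CDS", 1182),
    ]
    ir = [
        ("rpl2", "CDS", 1485, 1, (391, 434)), ("rpl23", "CDS", 282),
        t("trnI(CAU)"), t("trnL(CAA)"), ("ndhB", "CDS", 2210, 1, (775, 756)),
        ("rps7", "CDS", 468), ("rps12", "CDS", 372), t("trnV(GAC)"),
        ("rrn16", "rRNA", 1491), t("trnI(GAU)"), t("trnA(UGC)"),
        ("rrn23", "rRNA", 2810), ("rrn4.5", "rRNA", 103), ("rrn5", "rRNA", 121),
        t("trnR(ACG)"), t("trnN(GUU)"), t("trnG(GCC)"), ("rps19", "CDS", 279),
        ("ycf68", "CDS", 330),
    ]

    def scale_genes(defs):
        out = []
        for d in defs:
            g = GeneSpec(*d)
            if scale == 1.0:
                out.append(g)
                continue
            ln = max(9, int(g.length * scale) // 3 * 3)
            exons = ()
            if g.exons:
                ex = [max(3, int(x * scale) // 3 * 3) for x in g.exons]
                intron_total = ln - sum(ex)
                if intron_total < len(ex) - 1:  # keep at least 1 bp introns
                    ln = sum(ex) + len(ex) - 1
                exons = tuple(ex)
            out.append(replace(g, length=ln, exons=exons))
        return out

    return Architecture(
        lsc_len=int(83_000 * scale),
        ssc_len=int(12_800 * scale),
        ir_len=int(21_800 * scale),
        lsc_genes=scale_genes(lsc),
        ssc_genes=scale_genes(ssc),
        ir_genes=scale_genes(ir),
        junction_overhang=max(12, int(junction_overhang * scale)),
    )


def toy_architecture() -> Architecture:
    """A miniature genome (~7 kb) with the key marker spacers, for fast tests."""
    t = lambda n: (n, "tRNA", 60)
    lsc = _genes([
        ("psbA", "CDS", 300), t("trnK(UUU)"), ("rps16", "CDS", 210),
        t("trnY(GUA)"), t("trnD(GUC)"), ("psbM", "CDS", 90), t("trnS(UGA)"),
        t("trnC(GCA)"), ("rbcL", "CDS", 420), ("psaI", "CDS", 90),
        ("ycf4", "CDS", 180), ("cemA", "CDS", 210),
        ("rpl16", "CDS", 400, 1, (9, 150)),
    ])
    ssc = _genes([
        ("rps15", "CDS", 120), ("ndhF", "CDS", 360), ("rpl32", "CDS", 90),
        t("trnL(UAG)"), ("ndhH", "CDS", 300),
    ])
    ir = _genes([("rrn16", "rRNA", 400), t("trnV(GAC)"), ("rps19", "CDS", 150)])
    return Architecture(
        lsc_len=4200, ssc_len=1700, ir_len=1300,
        lsc_genes=lsc, ssc_genes=ssc, ir_genes=ir, junction_overhang=40,
    )


# ---------------------------------------------------------------------------
# layout


def _layout(arch: Architecture):
    """Place genes; returns (features, region_codes, mirror pairs)."""
    G = arch.genome_length
    lsc_lo, lsc_hi = 0, arch.lsc_len
    irb_lo, irb_hi = lsc_hi, lsc_hi + arch.ir_len
    ssc_lo, ssc_hi = irb_hi, irb_hi + arch.ssc_len
    ira_lo, ira_hi = ssc_hi, G
    code = np.full(G, NONCODING, dtype=np.int8)
    code[irb_lo:irb_hi] = IR
    code[ira_lo:ira_hi] = IR
    features: list[Feature] = []

    def place(genes, lo, hi, reserve_end=0):
        span = sum(g.length for g in genes)
        gaps = len(genes) + 1
        free = hi - lo - reserve_end - span
        if free < gaps:
            raise ValueError("architecture genes do not fit their region")
        base, rem = divmod(free, gaps)
        pos = lo
        placed = []
        for gi, g in enumerate(genes):
            pos += base + (1 if gi < rem else 0)
            placed.append((g, pos))
            pos += g.length
        return placed

    def add_gene(g: GeneSpec, start0: int, dup=False, mirror_in=None):
        """start0 is 0-based; mirror_in=(lo,hi) maps the gene into the IRa arm."""
        exon_lens = list(g.exons) if g.exons else [g.length]
        intron_total = g.length - sum(exon_lens)
        n_introns = max(len(exon_lens) - 1, 1) if intron_total else 0
        intron = intron_total // n_introns if n_introns else 0
        exons0 = []
        p = start0
        for i, ex in enumerate(exon_lens):
            exons0.append((p, p + ex))
            p += ex
            if i < len(exon_lens) - 1:
                p += intron + (intron_total - intron * n_introns if i == 0 else 0)
        ivs = [(s + 1, e, g.strand) for s, e in exons0]
        features.append(
            Feature("gene", g.name, [(start0 + 1, start0 + g.length, g.strand)], dup)
        )
        features.append(Feature(g.kind, g.name, ivs, dup))
        for s, e in exons0:
            seg = code[s:e]
            seg[seg != IR] = EXON
        if mirror_in:
            lo, hi = mirror_in
            ms = lo + (hi - (start0 + g.length))
            me = lo + (hi - start0)
            mivs = sorted(
                (lo + (hi - e) + 1, lo + (hi - s), -g.strand) for s, e in exons0
            )
            features.append(Feature("gene", g.name, [(ms + 1, me, -g.strand)], dup))
            features.append(Feature(g.kind, g.name, mivs, dup))

    for g, pos in place(arch.lsc_genes, lsc_lo, lsc_hi):
        add_gene(g, pos)
    # SSC: ndhH last, crossing into IRa by the junction overhang
    ov = arch.junction_overhang
    ndhh = arch.ssc_genes[-1]
    add_gene(ndhh, ssc_hi - (ndhh.length - ov))
    for g, pos in place(arch.ssc_genes[:-1], ssc_lo, ssc_hi - (ndhh.length - ov)):
        add_gene(g, pos)
    # IRb genes, mirrored into IRa; keep the SSC-adjacent end clear of the
    # ndhH overhang mirror
    for g, pos in place(arch.ir_genes, irb_lo, irb_hi, reserve_end=ov + 10):
        add_gene(g, pos, dup=True, mirror_in=(ira_lo, irb_hi))
    features.sort(key=lambda f: (f.start, f.kind != "gene"))
    intervals = {
        "lsc": (1, lsc_hi),
        "irb": (irb_lo + 1, irb_hi),
        "ssc": (ssc_lo + 1, ssc_hi),
        "ira": (ira_lo + 1, ira_hi),
    }
    return features, code, intervals


# ---------------------------------------------------------------------------
# simulation


def _random_seq(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def simulate(cfg: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run the generator; deterministic for a given config and seed."""
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    arch = cfg.architecture
    features, code, intervals = _layout(arch)
    G = arch.genome_length
    bases = _random_seq(rng, G, arch.gc)

    # named noncoding regions (spacers/introns) via the genome model itself
    tmp = GenomeRecord("root", bases.tobytes().decode(), features=list(features))
    spacers = {
        r.name: (r.start, r.end)
        for r in partition_regions(tmp, min_len=1)
        if r.cls == "noncoding"
    }
    for name in cfg.region_multipliers:
        if name not in spacers:
            raise ValueError(f"unknown region for rate multiplier: {name!r}")

    # pre-plant inversion arms in their spacers (root sequence surgery)
    inversion_sites = {}
    for ip in cfg.inversion_plants:
        if ip.region not in spacers:
            raise ValueError(f"unknown spacer for inversion plant: {ip.region!r}")
        s, e = spacers[ip.region]
        need = 2 * ip.arm + ip.segment
        if e - s + 1 < need + 2:
            raise ValueError(f"spacer {ip.region!r} too small for inversion plant")
        off = s - 1 + (e - s + 1 - need) // 2
        arm = _random_seq(rng, ip.arm, arch.gc)
        seg = _random_seq(rng, ip.segment, arch.gc)
        bases[off : off + ip.arm] = arm
        bases[off + ip.arm : off + ip.arm + ip.segment] = seg
        arm_rc = _COMP[arm][::-1]
        bases[off + ip.arm + ip.segment : off + need] = arm_rc
        code[off : off + need] = PROTECTED  # keep indels out of the locus
        inversion_sites[(ip.branch, ip.region)] = (
            off + ip.arm,
            off + ip.arm + ip.segment,
        )

    # IR mirroring and crisp junctions
    irb_lo, irb_hi = intervals["irb"][0] - 1, intervals["irb"][1]
    ira_lo, ira_hi = intervals["ira"][0] - 1, intervals["ira"][1]
    ssc_lo, ssc_hi = intervals["ssc"][0] - 1, intervals["ssc"][1]
    bases[ira_lo:ira_hi] = _COMP[bases[irb_lo:irb_hi]][::-1]
    if bases[ssc_lo] == _COMP[bases[ssc_hi - 1]]:
        choices = [b for b in b"ACGT" if b != _COMP[bases[ssc_hi - 1]]]
        bases[ssc_lo] = choices[int(rng.integers(len(choices)))]
    frozen = np.zeros(G, dtype=bool)
    frozen[[ssc_lo, ssc_hi - 1]] = True
    code = code.copy()
    code[frozen] = FROZEN

    # per-site substitution weights, normalized to mean 1
    w = np.where(
        code == EXON,
        cfg.coding_weight,
        np.where(code == IR, cfg.ir_weight, cfg.noncoding_weight),
    ).astype(float)
    for name, mult in cfg.region_multipliers.items():
        s, e = spacers[name]
        w[s - 1 : e] *= mult
    w[frozen] = 0.0
    w *= G / w.sum()
    # substitutions are drawn in IRb only and mirrored into IRa (concerted
    # evolution); zeroing IRa *after* normalization keeps the genome-wide
    # per-site rate equal to the branch length
    w[ira_lo:ira_hi] = 0.0

    mirror = {}
    for k in range(irb_hi - irb_lo):
        a, b = irb_lo + k, ira_hi - 1 - k
        mirror[a] = b
        mirror[b] = a

    # parse the tree
    dtree = dendropy.Tree.get(
        data=cfg.tree, schema="newick", preserve_underscores=True
    )
    taxa = sorted(lf.taxon.label for lf in dtree.leaf_node_iter())
    _anon = [0]

    def branch_name(nd):
        if nd.is_leaf():
            return nd.taxon.label
        if nd.label:
            return nd.label
        _anon[0] += 1
        return f"internal_{_anon[0]}"

    plants_by_branch: dict[str, list[RepeatPlant]] = {}
    for rp in cfg.repeat_plants:
        plants_by_branch.setdefault(rp.branch, []).append(rp)
    inv_by_branch: dict[str, list[InversionPlant]] = {}
    for ip in cfg.inversion_plants:
        inv_by_branch.setdefault(ip.branch, []).append(ip)

    next_id = [G]
    branch_logs: list[BranchLog] = []
    leaf_states: dict[str, tuple] = {}
    root_ids = list(range(G))
    root_bases = bases.tobytes().decode()

    def taxa_below(nd):
        if nd.is_leaf():
            return (nd.taxon.label,)
        return tuple(sorted(lf.taxon.label for lf in nd.leaf_iter()))

    def evolve_branch(state, nd, blen, name):
        ids, seq, wts, cds = state
        ids = ids.copy(); seq = seq.copy(); wts = wts.copy(); cds = cds.copy()
        blog = BranchLog(branch=name, length=blen, taxa_below=taxa_below(nd))
        L = len(ids)
        id_pos = None

        # --- substitutions -------------------------------------------------
        n_sub = rng.poisson(blen * wts.sum())
        if n_sub:
            p = wts / wts.sum()
            sites = rng.choice(L, size=n_sub, p=p)
            for site in sites:
                old = seq[site]
                if cfg.model == "K2P":
                    # transition with probability kappa/(kappa+2)
                    ts = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T
                    if rng.random() < cfg.kappa / (cfg.kappa + 2):
                        new = ts.get(int(old), int(old))
                        if new == old:
                            new = int(rng.choice([b for b in b"ACGT" if b != old]))
                    else:
                        tv = [b for b in b"ACGT" if b != old and b != ts.get(int(old))]
                        new = int(rng.choice(tv))
                else:
                    new = int(rng.choice([b for b in b"ACGT" if b != old]))
                seq[site] = new
                blog.substitutions.append((int(ids[site]), chr(old), chr(new)))
                if cds[site] == IR:
                    if id_pos is None:
                        id_pos = {int(v): i for i, v in enumerate(ids)}
                    mid = mirror.get(int(ids[site]))
                    mp = id_pos.get(mid) if mid is not None else None
                    if mp is not None:
                        mold = seq[mp]
                        seq[mp] = _COMP[new]
                        blog.substitutions.append(
                            (int(ids[mp]), chr(mold), chr(_COMP[new]))
                        )

        # --- indels (single-copy regions only) -----------------------------
        eligible = (cds == NONCODING) | (cds == EXON)
        n_ind = rng.poisson(cfg.indel_rate * blen * eligible.sum())
        for _ in range(n_ind):
            wel = wts * (
                (cds == NONCODING) + cfg.exon_indel_weight * (cds == EXON)
            )
            if wel.sum() == 0:
                break
            site = int(rng.choice(len(ids), p=wel / wel.sum()))
            in_exon = cds[site] == EXON
            if in_exon:
                ln = 3 * int(rng.geometric(0.5))
            else:
                ln = int(rng.geometric(1.0 / cfg.indel_mean))
            if rng.random() < 0.5:  # deletion, truncated at region boundaries
                end = site
                while end < len(ids) and end - site < ln and eligible[end] and cds[end] == cds[site]:
                    end += 1
                if end == site:
                    continue
                blog.deletions.append((tuple(int(x) for x in ids[site:end]),))
                keep = np.ones(len(ids), dtype=bool)
                keep[site:end] = False
                ids, seq, wts, cds = ids[keep], seq[keep], wts[keep], cds[keep]
                eligible = (cds == NONCODING) | (cds == EXON)
            else:  # insertion after the anchor site
                newb = _random_seq(rng, ln, arch.gc)
                new_ids = np.arange(next_id[0], next_id[0] + ln, dtype=np.int64)
                next_id[0] += ln
                at = site + 1
                ids = np.concatenate([ids[:at], new_ids, ids[at:]])
                seq = np.concatenate([seq[:at], newb, seq[at:]])
                wts = np.concatenate([wts[:at], np.full(ln, wts[site]), wts[at:]])
                cds = np.concatenate([cds[:at], np.full(ln, cds[site], dtype=cds.dtype), cds[at:]])
                eligible = (cds == NONCODING) | (cds == EXON)
                blog.insertions.append(
                    (int(ids[site]), tuple(int(x) for x in new_ids), newb.tobytes().decode())
                )

        # --- repeat plants (copies inserted into spacers, i.e. duplications) --
        def region_span(nm):
            """Current-coordinate span of a spacer (contiguous: everything
            between the surviving flanking spacer sites is still spacer)."""
            s, e = spacers[nm]
            sel = np.nonzero((ids >= s - 1) & (ids <= e - 1))[0]
            if len(sel) == 0:
                raise ValueError(f"spacer {nm!r} eroded away in simulation")
            return int(sel[0]), int(sel[-1])

        def insert_after(pos, payload):
            nonlocal ids, seq, wts, cds
            ln = len(payload)
            new_ids = np.arange(next_id[0], next_id[0] + ln, dtype=np.int64)
            next_id[0] += ln
            at = pos + 1
            anchor = int(ids[pos])
            ids = np.concatenate([ids[:at], new_ids, ids[at:]])
            seq = np.concatenate([seq[:at], payload, seq[at:]])
            wts = np.concatenate([wts[:at], np.full(ln, wts[pos]), wts[at:]])
            cds = np.concatenate(
                [cds[:at], np.full(ln, NONCODING, dtype=cds.dtype), cds[at:]]
            )
            blog.insertions.append(
                (anchor, tuple(int(x) for x in new_ids), payload.tobytes().decode())
            )

        for rp in plants_by_branch.get(name, []):
            s_lo, s_hi = region_span(rp.region)
            width = s_hi - s_lo + 1
            if width < rp.unit + 2:
                raise ValueError(f"spacer {rp.region!r} too small for plant {rp}")
            unit = seq[s_lo + 1 : s_lo + 1 + rp.unit].copy()
            if rp.kind == "dispersed":
                t_lo, t_hi = region_span(rp.target_region or rp.region)
                at = t_hi - 1 if rp.target_region == rp.region else t_lo
                insert_after(at, unit)
            elif rp.kind == "tandem":
                for _ in range(1, rp.copies):
                    insert_after(s_lo + rp.unit, unit)
            elif rp.kind == "palindromic":
                if width < rp.unit + rp.gap + 2:
                    raise ValueError(f"spacer {rp.region!r} too small for plant {rp}")
                insert_after(s_lo + rp.unit + rp.gap, _COMP[unit][::-1])
            else:
                raise ValueError(f"unknown repeat plant kind {rp.kind!r}")
            blog.repeat_plants.append(rp)
            eligible = (cds == NONCODING) | (cds == EXON)

        # --- inversions ------------------------------------------------------
        for ip in inv_by_branch.get(name, []):
            lo, hi = inversion_sites[(ip.branch, ip.region)]
            sel = np.nonzero((ids >= lo) & (ids < hi))[0]
            if len(sel):
                old = seq[sel].copy()
                seq[sel] = _COMP[old][::-1]
                blog.overwrites.append(
                    (tuple(int(ids[x]) for x in sel), seq[sel].tobytes().decode())
                )
            blog.inversions.append(ip)

        branch_logs.append(blog)
        return ids, seq, wts, cds

    root_state = (
        np.arange(G, dtype=np.int64),
        bases.copy(),
        w.copy(),
        code.copy(),
    )
    root_plants = plants_by_branch.get("root", [])
    if root_plants or "root" in inv_by_branch:

        class _RootNd:
            def is_leaf(self):
                return False

            def leaf_iter(self):
                class _T:
                    def __init__(self, lbl):
                        self.taxon = type("x", (), {"label": lbl})()

                return iter([_T(t) for t in taxa])

        root_state = evolve_branch(root_state, _RootNd(), 0.0, "root")
        # root-level edits become part of the root itself
        branch_logs.pop()
        root_ids = [int(x) for x in root_state[0]]
        root_bases = root_state[1].tobytes().decode()

    states = {dtree.seed_node: root_state}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        blen = nd.edge.length or 0.0
        states[nd] = evolve_branch(states[nd.parent_node], nd, blen, branch_name(nd))
        if nd.is_leaf():
            leaf_states[nd.taxon.label] = states[nd]
        else:
            pass
    for nd in list(states):  # free internal states
        if not nd.is_leaf():
            states.pop(nd, None)

    # --- leaf records -------------------------------------------------------
    records = {}
    quad_truth = {}
    for taxon in taxa:
        ids, seq, _, _ = leaf_states[taxon]
        id_pos = {int(v): i for i, v in enumerate(ids)}
        feats = []
        for f in features:
            ivs = []
            for s, e, strand in f.intervals:
                pos = [id_pos[i] for i in range(s - 1, e) if i in id_pos]
                if not pos:
                    continue
                ivs.append((min(pos) + 1, max(pos) + 1, strand))
            if ivs:
                feats.append(Feature(f.kind, f.name, sorted(ivs), f.is_duplicated))
        records[taxon] = GenomeRecord(
            id=taxon, seq=seq.tobytes().decode(), taxon=taxon, features=feats
        )
        qt = {}
        for rname, (s, e) in intervals.items():
            pos = [id_pos[i] for i in range(s - 1, e) if i in id_pos]
            qt[rname] = (min(pos) + 1, max(pos) + 1)
        quad_truth[taxon] = qt

    # --- true alignment ------------------------------------------------------
    def merge(a, b):
        bpos = {x: i for i, x in enumerate(b)}
        out, j = [], 0
        for x in a:
            if x in bpos:
                while j < bpos[x]:
                    out.append(b[j])
                    j += 1
                out.append(x)
                j = bpos[x] + 1
            else:
                out.append(x)
        out.extend(b[j:])
        return out

    order = list(root_ids)
    for taxon in taxa:
        order = merge(order, [int(x) for x in leaf_states[taxon][0]])
    colpos = {x: i for i, x in enumerate(order)}
    nL = len(order)
    rows = {}
    for taxon in taxa:
        ids, seq, _, _ = leaf_states[taxon]
        row = np.full(nL, ord("-"), dtype=np.uint8)
        row[[colpos[int(x)] for x in ids]] = seq
        rows[taxon] = row
    mat = np.vstack([rows[t] for t in taxa])
    mat = mat[:, (mat != ord("-")).any(axis=0)]  # drop columns absent in all leaves
    aln = AlignedSet(list(taxa), mat)

    truth = TruthLog(
        root_ids=root_ids,
        root_bases=root_bases,
        branches=branch_logs,
        region_names=sorted(spacers),
        spacer_intervals=spacers,
    )
    topo = Topology.from_newick(cfg.tree, taxa=taxa)
    root_rec = GenomeRecord("root", root_bases, features=list(features))
    return SimulationResult(
        config=cfg,
        records=records,
        alignment=aln,
        truth=truth,
        tree=topo,
        root_record=root_rec,
        quadripartite_truth=quad_truth,
    )


def plant_markers(cfg: SimulationConfig, hot_regions, fold: float) -> SimulationConfig:
    """Return a config with substitution/indel rates multiplied in named regions."""
    features, _, _ = _layout(cfg.architecture)
    tmp = GenomeRecord(
        "x", "A" * cfg.architecture.genome_length, features=list(features)
    )
    names = {r.name for r in partition_regions(tmp, min_len=1)}
    mult = dict(cfg.region_multipliers)
    for name in hot_regions:
        if name not in names:
            raise ValueError(f"unknown region: {name!r}")
        mult[name] = mult.get(name, 1.0) * fold
    return replace(cfg, region_multipliers=mult)


# ---------------------------------------------------------------------------
# study-scale defaults


BAMBOO_TREE = (
    "((Bambusa_emeiensis:0.0016,(Bambusa_oldhamii:0.0012,"
    "Dendrocalamus_latiflorus:0.0012)Bambusa_core:0.0004)Bambuseae:0.0060,"
    "(Ferrocalamus_rimosivaginus:0.0011,(Acidosasa_purpurea:0.0009,"
    "(Indocalamus_longiauritus:0.0008,(Phyllostachys_edulis:0.0005,"
    "Phyllostachys_nigra:0.0005)Phyllostachys_pair:0.0003)"
    "Phyllostachys_clade:0.0002)Arundinaria_core:0.0002)Arundinarieae:0.0060);"
)

BAMBOO_GROUPS = {
    "Bambusa_emeiensis": "Bambuseae",
    "Bambusa_oldhamii": "Bambuseae",
    "Dendrocalamus_latiflorus": "Bambuseae",
    "Ferrocalamus_rimosivaginus": "Arundinarieae",
    "Acidosasa_purpurea": "Arundinarieae",
    "Indocalamus_longiauritus": "Arundinarieae",
    "Phyllostachys_edulis": "Arundinarieae",
    "Phyllostachys_nigra": "Arundinarieae",
}

SIX_TAXON_TREE = (
    "(Bambusa_emeiensis:0.0076,(Ferrocalamus_rimosivaginus:0.0011,"
    "(Acidosasa_purpurea:0.0009,(Indocalamus_longiauritus:0.0008,"
    "(Phyllostachys_edulis:0.0005,Phyllostachys_nigra:0.0005)"
    "Phyllostachys_pair:0.0003)Phyllostachys_clade:0.0002)"
    "Arundinaria_core:0.0002)Arundinarieae:0.0060);"
)


def default_repeat_plants() -> list[RepeatPlant]:
    """A repeat history echoing the published pattern: a core of repeats shared
    by every taxon, a block shared by the temperate clade, and unique repeats
    concentrated in Bambusa emeiensis with none in Phyllostachys edulis."""
    P = RepeatPlant
    return [
        # shared by all (planted above the root)
        P("root", "tandem", 18, "trnK(UUU)-rps16"),
        P("root", "tandem", 22, "rbcL-psaI"),
        P("root", "dispersed", 34, "trnY(GUA)-trnD(GUC)", "trnD(GUC)-psbM"),
        P("root", "dispersed", 42, "psbM-petN", "rpoB-rpoC1"),
        P("root", "palindromic", 21, "atpB-rbcL", gap=60),
        P("root", "palindromic", 24, "ycf4-cemA", gap=90),
        # tribe stems
        P("Bambuseae", "tandem", 16, "psbA-matK"),
        P("Bambuseae", "dispersed", 31, "rps16-trnQ(UUG)", "trnQ(UUG)-psbK"),
        P("Arundinarieae", "tandem", 20, "petA-psbJ"),
        P("Arundinarieae", "dispersed", 36, "rps2-atpI", "atpI-atpH"),
        P("Arundinarieae", "palindromic", 22, "clpP-psbB", gap=50),
        P("Arundinarieae", "tandem", 15, "rpoC2-rps2"),
        # nested clades
        P("Arundinaria_core", "tandem", 17, "petN-trnS(UGA)"),
        P("Arundinaria_core", "dispersed", 37, "infA-rps8", "rpl14-rpl16"),
        P("Phyllostachys_clade", "tandem", 17, "psaJ-rpl33"),
        P("Phyllostachys_clade", "dispersed", 33, "petD-rpoA", "rpoA-rps11"),
        P("Phyllostachys_pair", "tandem", 19, "psbE-petL"),
        P("Phyllostachys_pair", "dispersed", 30, "ndhC-trnV(UAC)", "atpE-atpB"),
        P("Bambusa_core", "tandem", 21, "psbH-petB"),
        # terminal (unique) repeats; none on Phyllostachys_edulis
        P("Bambusa_emeiensis", "tandem", 25, "rpl20-clpP"),
        P("Bambusa_emeiensis", "dispersed", 40, "psbC-psbZ", "rps14-psaB"),
        P("Bambusa_emeiensis", "dispersed", 55, "rpl33-rps18", "rps18-rpl20"),
        P("Bambusa_emeiensis", "palindromic", 23, "trnS(UGA)-trnC(GCA)", gap=70),
        P("Bambusa_emeiensis", "tandem", 15, "psbI-trnS(GCA)"),
        P("Bambusa_oldhamii", "tandem", 16, "atpH-atpF"),
        P("Dendrocalamus_latiflorus", "dispersed", 32, "ycf3-trnS(GGA)", "rps4-trnT(UGU)"),
        P("Ferrocalamus_rimosivaginus", "tandem", 24, "psaB-psaA"),
        P("Ferrocalamus_rimosivaginus", "palindromic", 20, "petG-trnW(CCA)", gap=45),
        P("Acidosasa_purpurea", "tandem", 18, "cemA-petA"),
        P("Indocalamus_longiauritus", "dispersed", 38, "psbB-psbT", "psbN-psbH"),
        P("Phyllostachys_nigra", "tandem", 65, "rpoC1-rpoC2"),
    ]


def default_inversion_plants() -> list[InversionPlant]:
    return [
        InversionPlant("Phyllostachys_pair", "rpl32-trnL(UAG)", arm=20, segment=24),
        InversionPlant("Bambusa_emeiensis", "ndhF-rpl32", arm=20, segment=22),
    ]


def bamboo_like_config(
    scale: float = 1.0,
    tree: str = BAMBOO_TREE,
    with_plants: bool = True,
    seed: int | None = None,
) -> SimulationConfig:
    """Study-scale defaults: architecture, divergence, repeats and inversions
    all anchored to the published six-bamboo comparison."""
    return SimulationConfig(
        tree=tree,
        architecture=default_architecture(scale=scale),
        repeat_plants=default_repeat_plants() if with_plants else [],
        inversion_plants=default_inversion_plants() if with_plants else [],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# direct repeat-matrix simulation (for tree-recovery experiments)


def simulate_repeat_matrix(
    tree: str | Topology,
    n_informative: int = 30,
    n_autapomorphic: int = 10,
    homoplasy_prob: float = 0.05,
    seed: int = 0,
):
    """Binary presence/absence characters born on the branches of a known tree.

    Informative characters gain the derived state on an internal edge (the
    clade below carries 1); autapomorphic characters gain on a terminal edge.
    With probability ``homoplasy_prob`` a random taxon's state is flipped,
    introducing homoplasy.  Returns (CharacterMatrix, generating Topology).
    """
    topo = tree if isinstance(tree, Topology) else Topology.from_newick(tree)
    rng = np.random.default_rng(seed)
    taxa = list(topo.taxa)
    clades = [sorted(b) for b in topo.bipartitions()]
    cols: list[dict] = []
    while sum(1 for c in cols if _informative(c, taxa)) < n_informative:
        clade = clades[int(rng.integers(len(clades)))]
        col = {t: ("1" if t in clade else "0") for t in taxa}
        if rng.random() < homoplasy_prob:
            t = taxa[int(rng.integers(len(taxa)))]
            col[t] = "0" if col[t] == "1" else "1"
        cols.append(col)
    for _ in range(n_autapomorphic):
        t = taxa[int(rng.integers(len(taxa)))]
        cols.append({x: ("1" if x == t else "0") for x in taxa})
    rows = ["".join(c[t] for c in cols) for t in taxa]
    return CharacterMatrix(taxa, rows, kind="standard"), topo


def _informative(col, taxa):
    ones = sum(1 for t in taxa if col[t] == "1")
    return 2 <= ones <= len(taxa) - 2
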