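"""Fitch parsimony on discrete character matrices over unrooted binary trees.

Tree length is the minimum number of unordered state changes summed over
characters; CI = m/s and RI = (g - s)/(g - m) where m and g are the sums of
per-character minimum and maximum conceivable steps.  Uninformative characters
are included in CI/RI (the convention of the classic parsimony programs).
Exhaustive search enumerates all unrooted binary topologies (4-9 taxa; 105 at
six taxa); a stepwise-addition + NNI heuristic covers larger matrices.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

MISSING = {"?", "N", "n"}


@dataclass
class CharacterMatrix:
    """Taxa x characters; rows are strings of single-symbol states.

    '?' (and 'N' in DNA matrices) is missing; '-' is treated as missing when
    gaps are excluded from scoring (the default for DNA) and as a state
    otherwise.
    """

    taxa: list[str]
    rows: list[str]
    kind: str = "standard"  # standard | dna
    labels: list[str] | None = None

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, j: int) -> dict:
        return {t: r[j] for t, r in zip(self.taxa, self.rows)}

    def subset(self, taxa: list[str]) -> "CharacterMatrix":
        return CharacterMatrix(
            list(taxa), [self.row(t) for t in taxa], self.kind, self.labels
        )

    def append_characters(self, new_cols: dict[str, str], labels=None) -> "CharacterMatrix":
        """Append binary/other characters given as taxon -> suffix string."""
        k = len(next(iter(new_cols.values())))
        rows = [r + new_cols.get(t, "?" * k) for t, r in zip(self.taxa, self.rows)]
        lab = None
        if self.labels is not None or labels is not None:
            lab = (self.labels or [str(i) for i in range(self.n_chars)]) + (
                labels or [f"x{i}" for i in range(k)]
            )
        return CharacterMatrix(list(self.taxa), rows, self.kind, lab)

    def encode(self, gaps_missing: bool = True):
        """Bitmask encoding (n_taxa x n_chars uint8); missing/gap -> 255."""
        E = np.zeros((self.n_taxa, self.n_chars), dtype=np.uint8)
        for j in range(self.n_chars):
            col = [r[j] for r in self.rows]
            missing = set(MISSING) | ({"-"} if gaps_missing else set())
            symbols = sorted({s for s in col if s not in missing})
            if len(symbols) > 8:
                raise ValueError(f"more than 8 states in column {j}")
            bit = {s: 1 << i for i, s in enumerate(symbols)}
            for i, s in enumerate(col):
                E[i, j] = bit.get(s, 255)
        return E


@dataclass(frozen=True)
class ParsimonyScore:
    s: int  # observed steps (tree length)
    m: int  # sum of per-character minimum steps
    g: int  # sum of per-character maximum steps
    ci: float  # consistency index m/s
    ri: float  # retention index (g-s)/(g-m); nan when g == m


# ---------------------------------------------------------------------------
# topologies


class Topology:
    """Unrooted binary tree over unique taxon labels.

    Leaves are indexed 0..n-1 in the order of ``taxa``; internal nodes get ids
    n..2n-3.  Equality and hashing go through the bipartition set, so the same
    unrooted shape compares equal however it was built.
    """

    def __init__(self, taxa, edges):
        self.taxa = tuple(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        self.edges = tuple(sorted(tuple(sorted(e)) for e in edges))
        self._adj: dict[int, list[int]] = {}
        for u, v in self.edges:
            self._adj.setdefault(u, []).append(v)
            self._adj.setdefault(v, []).append(u)
        n = len(self.taxa)
        if n >= 3:
            for node, nb in self._adj.items():
                deg = len(nb)
                if node < n and deg != 1:
                    raise ValueError("leaf with degree != 1")
                if node >= n and deg != 3:
                    raise ValueError("internal node with degree != 3 (unrooted binary)")
        self._bips = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def neighbors(self, node: int):
        return self._adj[node]

    def _side(self, u: int, v: int) -> frozenset:
        """Taxa reachable from v when the edge u-v is cut."""
        seen, stack, leaves = {u, v}, [v], []
        while stack:
            x = stack.pop()
            if x < self.n_taxa:
                leaves.append(self.taxa[x])
            for y in self._adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(leaves)

    def bipartitions(self) -> frozenset:
        """Non-trivial splits, each canonicalized as the side without taxa[0]."""
        if self._bips is None:
            bips = set()
            for u, v in self.edges:
                if u < self.n_taxa or v < self.n_taxa:
                    continue
                side = self._side(u, v)
                if self.taxa[0] in side:
                    side = frozenset(self.taxa) - side
                bips.add(side)
            self._bips = frozenset(bips)
        return self._bips

    def __eq__(self, other):
        return (
            isinstance(other, Topology)
            and set(self.taxa) == set(other.taxa)
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self):
        return hash((frozenset(self.taxa), self.bipartitions()))

    def __repr__(self):
        return f"Topology({self.newick()})"

    # -- newick -----------------------------------------------------------

    def newick(self, outgroup: str | None = None) -> str:
        og = self.taxa.index(outgroup) if outgroup else 0
        root = self._adj[og][0]

        def sub(node, parent):
            if node < self.n_taxa:
                return self.taxa[node]
            kids = [sub(c, node) for c in self._adj[node] if c != parent]
            return "(" + ",".join(kids) + ")"

        kids = [sub(c, root) for c in self._adj[root] if c != og]
        return f"({self.taxa[og]},{','.join(kids)});"

    @classmethod
    def from_newick(cls, s: str, taxa=None) -> "Topology":
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
        tree.is_rooted = False
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        taxa = list(taxa) if taxa else sorted(leaves)
        if set(taxa) != set(leaves):
            raise ValueError("taxa do not match newick leaves")
        idx = {t: i for i, t in enumerate(taxa)}
        next_id = [len(taxa)]
        ids: dict = {}

        def node_id(nd):
            if nd not in ids:
                if nd.is_leaf():
                    ids[nd] = idx[nd.taxon.label]
                else:
                    ids[nd] = next_id[0]
                    next_id[0] += 1
            return ids[nd]

        edges = []
        seed = tree.seed_node
        # collapse a degree-2 seed node (rooted newick of an unrooted tree)
        skip = seed if len(seed.child_nodes()) == 2 else None
        for nd in tree.preorder_node_iter():
            for ch in nd.child_nodes():
                if nd is skip:
                    continue
                edges.append((node_id(nd), node_id(ch)))
        if skip is not None:
            a, b = skip.child_nodes()
            edges.append((node_id(a), node_id(b)))
        return cls(taxa, edges)


def enumerate_topologies(taxa):
    """All unrooted binary topologies (3 taxa: 1; 6 taxa: 105; n<=9 supported)."""
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    def build(k, edges, next_internal):
        if k == n:
            yield Topology(taxa, edges)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            m = next_internal
            rest = edges[:i] + edges[i + 1 :]
            yield from build(k + 1, rest + [(u, m), (v, m), (k, m)], m + 1)

    first = n  # first internal node id
    yield from build(3, [(0, first), (1, first), (2, first)], first + 1)


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n labelled taxa."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


# ---------------------------------------------------------------------------
# Fitch scoring


def _program(t: Topology):
    """Postorder op list for vectorized Fitch, rooted at a leaf's neighbor."""
    leaf = min(x for x in t._adj if x < t.n_taxa)
    root = t.neighbors(leaf)[0]
    ops = []  # (left_slot, right_slot, target_slot)

    def visit(node, parent):
        if node < t.n_taxa:
            return node
        kids = [visit(c, node) for c in t.neighbors(node) if c != parent]
        ops.append((kids[0], kids[1], node))
        return node

    visit(root, leaf)
    ops.append((leaf, root, None))  # final union check against the root leaf
    return ops


def _run_fitch(E: np.ndarray, weights, ops, n_slots):
    C = E.shape[1]
    S = np.zeros((n_slots, C), dtype=np.uint8)
    S[: E.shape[0]] = E
    if weights is None:
        weights = np.ones(C)
    total = 0.0
    for left, right, target in ops:
        inter = S[left] & S[right]
        zero = inter == 0
        if target is None:
            total += weights[zero].sum()
        else:
            S[target] = np.where(zero, S[left] | S[right], inter)
            total += weights[zero].sum()
    return total


def fitch_length(
    t: Topology, M: CharacterMatrix, weights=None, gaps_missing: bool | None = None
) -> float:
    """Fitch tree length of the matrix on one topology.

    Gaps are excluded (treated as missing) for DNA matrices by default and
    kept as states for standard matrices; '?' is always missing.
    """
    if set(M.taxa) != set(t.taxa):
        raise ValueError("matrix taxa do not match tree taxa")
    if gaps_missing is None:
        gaps_missing = M.kind == "dna"
    E = M.subset(list(t.taxa)).encode(gaps_missing=gaps_missing)
    ops = _program(t)
    total = _run_fitch(E, weights, ops, 2 * t.n_taxa - 2)
    return float(total) if weights is not None else int(total)


def _min_max_steps(M: CharacterMatrix, gaps_missing: bool):
    miss = set(MISSING) | ({"-"} if gaps_missing else set())
    ms, gs = [], []
    for j in range(M.n_chars):
        col = [r[j] for r in M.rows if r[j] not in miss]
        if not col:
            ms.append(0)
            gs.append(0)
            continue
        counts = {}
        for s in col:
            counts[s] = counts.get(s, 0) + 1
        ms.append(len(counts) - 1)
        gs.append(len(col) - max(counts.values()))
    return np.array(ms), np.array(gs)


def score_stats(t: Topology, M: CharacterMatrix, gaps_missing: bool | None = None) -> ParsimonyScore:
    """Tree length with CI and RI (uninformative characters included)."""
    if gaps_missing is None:
        gaps_missing = M.kind == "dna"
    s = int(fitch_length(t, M, gaps_missing=gaps_missing))
    ms, gs = _min_max_steps(M, gaps_missing)
    m, g = int(ms.sum()), int(gs.sum())
    if not m <= s <= g:
        raise AssertionError("parsimony bound violated (m <= s <= g)")
    ci = m / s if s > 0 else float("nan")
    ri = (g - s) / (g - m) if g > m else float("nan")
    return ParsimonyScore(s=s, m=m, g=g, ci=ci, ri=ri)


# ---------------------------------------------------------------------------
# search


MAX_EXHAUSTIVE_TAXA = 9


def exhaustive_search(M: CharacterMatrix, weights=None, gaps_missing: bool | None = None):
    """All minimum-length topologies plus the score of the optimum.

    Restricted to 4..9 taxa (105 topologies at n=6, 135,135 at n=9); larger
    matrices should use :func:`heuristic_search`.
    """
    n = M.n_taxa
    if not 4 <= n <= MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"exhaustive search supports 4..{MAX_EXHAUSTIVE_TAXA} taxa "
            f"(got {n}); use heuristic_search"
        )
    if gaps_missing is None:
        gaps_missing = M.kind == "dna"
    E = M.encode(gaps_missing=gaps_missing)
    best, opts = None, []
    for t in enumerate_topologies(M.taxa):
        ln = _run_fitch(E, weights, _program(t), 2 * n - 2)
        if best is None or ln < best - 1e-9:
            best, opts = ln, [t]
        elif abs(ln - best) <= 1e-9:
            opts.append(t)
    score = score_stats(opts[0], M, gaps_missing=gaps_missing) if weights is None else None
    return opts, score


def heuristic_search(M: CharacterMatrix, weights=None, seed: int = 0, n_starts: int = 5):
    """Stepwise addition + NNI hill climbing for matrices with > 9 taxa."""
    rng = np.random.default_rng(seed)
    gaps_missing = M.kind == "dna"
    E = M.encode(gaps_missing=gaps_missing)
    n = M.n_taxa

    def length(t):
        return _run_fitch(E, weights, _program(t), 2 * n + 2)

    def stepwise(order):
        taxa = list(M.taxa)
        # build on full taxa list; attach in 'order'
        edges = None
        next_internal = n
        placed = list(order[:3])
        edges = [(order[0], next_internal), (order[1], next_internal), (order[2], next_internal)]
        next_internal += 1
        for k in order[3:]:
            best_e, best_len = None, None
            for i, (u, v) in enumerate(edges):
                cand = edges[:i] + edges[i + 1 :] + [
                    (u, next_internal), (v, next_internal), (k, next_internal)
                ]
                t = Topology(taxa, cand)
                ln = length(t)
                if best_len is None or ln < best_len:
                    best_e, best_len = cand, ln
            edges = best_e
            next_internal += 1
        return Topology(list(M.taxa), edges)

    def nni(t):
        improved = True
        cur, cur_len = t, length(t)
        while improved:
            improved = False
            for u, v in cur.edges:
                if u < n or v < n:
                    continue
                for cand in _nni_neighbors(cur, u, v):
                    ln = length(cand)
                    if ln < cur_len - 1e-9:
                        cur, cur_len = cand, ln
                        improved = True
                        break
                if improved:
                    break
        return cur, cur_len

    best_t, best_len = None, None
    for _ in range(n_starts):
        order = list(rng.permutation(n))
        t, ln = nni(stepwise(order))
        if best_len is None or ln < best_len:
            best_t, best_len = t, ln
    return best_t, best_len


def _nni_neighbors(t: Topology, u: int, v: int):
    """The two nearest-neighbour interchanges across internal edge u-v."""
    au = [x for x in t.neighbors(u) if x != v]
    av = [x for x in t.neighbors(v) if x != u]
    for swap in (av[0], av[1]):
        drop = {tuple(sorted((u, au[1]))), tuple(sorted((v, swap)))}
        edges = [e for e in t.edges if tuple(sorted(e)) not in drop]
        edges += [(u, swap), (v, au[1])]
        yield Topology(t.taxa, edges)


# ---------------------------------------------------------------------------
# bootstrap & consensus


def bootstrap(M: CharacterMatrix, reps: int = 1000, seed: int = 0, gaps_missing=None):
    """Nonparametric bootstrap support (%) per non-trivial bipartition.

    Characters are resampled with replacement; each replicate is solved by
    exhaustive search and contributes the bipartitions of the *strict
    consensus* of its co-optimal trees (so splits not pinned down by a
    replicate add no support).  Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = M.n_taxa
    if not 4 <= n <= MAX_EXHAUSTIVE_TAXA:
        raise ValueError("bootstrap uses exhaustive search; 4..9 taxa only")
    if gaps_missing is None:
        gaps_missing = M.kind == "dna"
    E = M.encode(gaps_missing=gaps_missing)
    C = M.n_chars
    topos = list(enumerate_topologies(M.taxa))
    progs = [_program(t) for t in topos]
    bips = [t.bipartitions() for t in topos]
    rng = np.random.default_rng(seed)
    support: dict = {}
    for _ in range(reps):
        w = np.bincount(rng.integers(0, C, C), minlength=C).astype(float)
        best, opt_idx = None, []
        for i, prog in enumerate(progs):
            ln = _run_fitch(E, w, prog, 2 * n - 2)
            if best is None or ln < best - 1e-9:
                best, opt_idx = ln, [i]
            elif abs(ln - best) <= 1e-9:
                opt_idx.append(i)
        common = bips[opt_idx[0]]
        for i in opt_idx[1:]:
            common = common & bips[i]
        for b in common:
            support[b] = support.get(b, 0.0) + 1.0
    return {b: 100.0 * v / reps for b, v in support.items()}


def strict_consensus(trees) -> frozenset:
    """Bipartitions common to every input tree."""
    trees = list(trees)
    out = trees[0].bipartitions()
    for t in trees[1:]:
        out = out & t.bipartitions()
    return out


# ---------------------------------------------------------------------------
# character mapping


@dataclass
class CharacterFate:
    character: str
    derived_taxa: tuple
    origins: int
    classification: str  # synapomorphic | homoplasious
    polarity: str | None  # '+' insertion / '-' deletion / None undetermined
    polarity_flagged: bool = False


def map_character(
    t: Topology, states: dict, outgroup: str, character: str = "", polarity_map=None
) -> CharacterFate:
    """Parsimony-map one binary character on a fixed topology.

    The outgroup carries the ancestral state; origins is the Fitch length of
    the character, and the character is synapomorphic iff it arises once.
    ``polarity_map`` optionally translates the derived state to '+'/'-'.
    """
    if outgroup not in t.taxa:
        raise ValueError(f"outgroup {outgroup!r} not on the tree")
    rows = [states.get(tx, "?") for tx in t.taxa]
    M = CharacterMatrix(list(t.taxa), rows, kind="standard")
    origins = int(fitch_length(t, M, gaps_missing=False))
    anc = states.get(outgroup, "?")
    flagged = anc in MISSING or anc == "?"
    derived_state = None if flagged else ("1" if anc == "0" else "0")
    derived = tuple(
        tx for tx in t.taxa
        if tx != outgroup and derived_state is not None and states.get(tx) == derived_state
    )
    polarity = None
    if polarity_map and derived_state is not None:
        polarity = polarity_map.get(derived_state)
    cls = "synapomorphic" if origins == 1 else "homoplasious"
    return CharacterFate(
        character=character,
        derived_taxa=derived,
        origins=origins,
        classification=cls,
        polarity=polarity,
        polarity_flagged=flagged,
    )


# ---------------------------------------------------------------------------
# I/O


def write_nexus(M: CharacterMatrix, path) -> None:
    sym = "ACGT" if M.kind == "dna" else "01"
    dt = "DNA" if M.kind == "dna" else "STANDARD"
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={M.n_taxa} NCHAR={M.n_chars};\n")
        fh.write(f"  FORMAT DATATYPE={dt} GAP=- MISSING=? SYMBOLS=\"{sym}\";\n")
        fh.write("  MATRIX\n")
        w = max(len(t) for t in M.taxa) + 2
        for t, r in zip(M.taxa, M.rows):
            fh.write(f"    {t.replace(' ', '_'):<{w}}{r}\n")
        fh.write("  ;\nEND;\n")


def read_nexus(path) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        kind = "standard"
    except Exception:
        dm = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
        kind = "dna"
    taxa = [t.label.replace(" ", "_") for t in dm.taxon_namespace]
    rows = [str(dm[t]).replace(" ", "") for t in dm.taxon_namespace]
    return CharacterMatrix(taxa, rows, kind=kind)


def write_newick(t: Topology, path, outgroup: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(t.newick(outgroup=outgroup) + "\n")


def read_newick(path, taxa=None) -> Topology:
    with open(path) as fh:
        return Topology.from_newick(fh.read(), taxa=taxa)
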