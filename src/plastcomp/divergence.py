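"""Sequence divergence: p-distances, identity profiles, per-region variability,
marker ranking and the PI-vs-variability regression.

The variability statistic follows the mutation-event proportion
``variation% = 100 * (NS + ID) / L`` where NS counts column-level substitution
events (distinct non-gap states minus one per variable column), ID counts
distinct indel events (maximal gap runs with identical boundaries collapse to
one event) and L is the aligned length.  Parsimony-informative (PI) sites are
columns with at least two states each carried by at least two taxa.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

from ._seq import _CODE
from .genome import Region, RegionSet

GAP = ord("-")


@dataclass
class AlignedSet:
    """A multiple alignment: equal-length rows over {A,C,G,T,N,-}."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, L) uint8 ASCII

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least two rows")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data shape does not match taxa")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.data[self.taxa.index(taxon)].tobytes().decode("ascii")

    def subset(self, taxa) -> "AlignedSet":
        idx = [self.taxa.index(t) for t in taxa]
        return AlignedSet(list(taxa), self.data[idx])

    def slice_columns(self, cols) -> "AlignedSet":
        return AlignedSet(list(self.taxa), self.data[:, cols])

    @classmethod
    def from_dict(cls, rows: dict[str, str]) -> "AlignedSet":
        taxa = list(rows)
        lens = {len(v) for v in rows.values()}
        if len(lens) != 1:
            raise ValueError("rows must have equal length")
        data = np.frombuffer("".join(rows.values()).upper().encode(), dtype=np.uint8)
        return cls(taxa, data.reshape(len(taxa), lens.pop()).copy())

    @classmethod
    def from_fasta(cls, path) -> "AlignedSet":
        aln = AlignIO.read(str(path), "fasta")
        return cls.from_dict({r.id: str(r.seq) for r in aln})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n")
                row = self.row(t)
                for i in range(0, len(row), 70):
                    fh.write(row[i : i + 70] + "\n")


@dataclass
class DistanceSummary:
    matrix: pd.DataFrame  # symmetric, zero diagonal
    overall_mean: float
    within: dict  # group -> mean of intra-group pair distances
    between: dict  # (group1, group2) -> mean of inter-group pair distances
    groups: dict | None
    undefined_pairs: list


@dataclass
class RegionStats:
    region: str
    cls: str  # coding | noncoding
    length: int  # aligned length L
    ns: int  # substitution events
    indels: int  # indel events
    variable_sites: int
    pi_sites: int
    variation_pct: float
    pi_pct: float


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


# ---------------------------------------------------------------------------


def p_distance(aln: AlignedSet, groups: dict | None = None) -> DistanceSummary:
    """Uncorrected pairwise distances with pairwise deletion.

    Columns with a gap, N or other ambiguity in either row of a pair are
    excluded from that pair's comparison (the classic pairwise-deletion
    convention).  Group means are arithmetic means of the relevant pairwise
    values; the overall mean is the mean over all pairs, which makes it an
    exact pair-count-weighted mean of the within- and between-group values.
    """
    codes = _CODE[aln.data]  # ACGT -> 0..3, everything else 4
    n = aln.n_taxa
    D = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4)
            m = int(ok.sum())
            if m == 0:
                D[i, j] = D[j, i] = np.nan
                undefined.append((aln.taxa[i], aln.taxa[j]))
                continue
            diff = int((codes[i][ok] != codes[j][ok]).sum())
            D[i, j] = D[j, i] = diff / m
    df = pd.DataFrame(D, index=aln.taxa, columns=aln.taxa)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [D[i, j] for i, j in pairs]
    finite = [v for v in vals if not np.isnan(v)]
    overall = float(np.mean(finite)) if finite else float("nan")
    within, between = {}, {}
    if groups:
        bygroup: dict = {}
        for i, j in pairs:
            gi, gj = groups.get(aln.taxa[i]), groups.get(aln.taxa[j])
            if gi is None or gj is None:
                continue
            key = gi if gi == gj else tuple(sorted((gi, gj)))
            bygroup.setdefault(key, []).append(D[i, j])
        for key, v in bygroup.items():
            (within if isinstance(key, str) else between)[key] = float(np.nanmean(v))
    return DistanceSummary(df, overall, within, between, groups, undefined)


def identity_profile(
    aln: AlignedSet, reference: str, window: int = 100, step: int = 25
) -> pd.DataFrame:
    """Sliding-window identity (%) of each row against a reference row.

    Coordinates are reference-anchored: columns gapped in the reference are
    collapsed first.  A base matches only when identical and unambiguous, so
    gaps and Ns count as differences.  Returns a DataFrame indexed by 1-based
    window start.
    """
    ridx = aln.taxa.index(reference)
    keep = aln.data[ridx] != GAP
    sub = aln.data[:, keep]
    codes = _CODE[sub]
    L = sub.shape[1]
    ref = codes[ridx]
    starts = list(range(0, max(L - window, 0) + 1, step)) or [0]
    if L < window:
        starts = [0]
    rows = {}
    for ti, taxon in enumerate(aln.taxa):
        if taxon == reference:
            continue
        match = (codes[ti] == ref) & (ref < 4) & (codes[ti] < 4)
        cum = np.concatenate([[0], np.cumsum(match)])
        vals = []
        for s in starts:
            e = min(s + window, L)
            vals.append(100.0 * (cum[e] - cum[s]) / (e - s))
        rows[taxon] = vals
    return pd.DataFrame(rows, index=pd.Index([s + 1 for s in starts], name="start"))


def _gap_runs(row: np.ndarray):
    """Maximal gap runs as (start, end) 0-based inclusive; full-row runs excluded."""
    isgap = row == GAP
    if isgap.all():
        return []
    d = np.diff(isgap.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if isgap[0]:
        starts.insert(0, 0)
    if isgap[-1]:
        ends.append(len(row) - 1)
    return list(zip(starts, ends))


def region_variability(
    aln: AlignedSet, count_indels: bool = True, name: str = "", cls: str = ""
) -> RegionStats:
    """Per-region alignment statistics and the mutation-event proportion."""
    L = aln.length
    if L == 0:
        raise ValueError("empty region alignment")
    codes = _CODE[aln.data]
    ns = variable = pi = 0
    for j in range(L):
        col = codes[:, j]
        col = col[col < 4]
        if len(col) == 0:
            continue
        counts = np.bincount(col, minlength=4)
        k = int((counts > 0).sum())
        if k >= 2:
            variable += 1
            ns += k - 1
            if int((counts >= 2).sum()) >= 2:
                pi += 1
    runs = set()
    for i in range(aln.n_taxa):
        runs.update(_gap_runs(aln.data[i]))
    indels = len(runs)
    events = ns + (indels if count_indels else 0)
    return RegionStats(
        region=name,
        cls=cls,
        length=L,
        ns=ns,
        indels=indels,
        variable_sites=variable,
        pi_sites=pi,
        variation_pct=100.0 * events / L,
        pi_pct=100.0 * pi / L,
    )


def rank_markers(stats: list[RegionStats], k: int = 20,
                 variation_threshold: float = 4.0, pi_threshold: float = 3.0):
    """Rank candidate marker regions by variability.

    Descending variation%, ties broken by PI% then name.  Returns the ranked
    table (top ``k``) plus how many regions exceed the variation threshold and
    how many of those also exceed the PI threshold.
    """
    ordered = sorted(stats, key=lambda r: (-r.variation_pct, -r.pi_pct, r.region))
    df = pd.DataFrame(
        {
            "region": [r.region for r in ordered],
            "class": [r.cls for r in ordered],
            "length": [r.length for r in ordered],
            "NS": [r.ns for r in ordered],
            "ID": [r.indels for r in ordered],
            "variable_sites": [r.variable_sites for r in ordered],
            "PI_sites": [r.pi_sites for r in ordered],
            "variation_pct": [r.variation_pct for r in ordered],
            "pi_pct": [r.pi_pct for r in ordered],
        }
    )
    above = df[df.variation_pct > variation_threshold]
    n_var = int(len(above))
    n_pi = int((above.pi_pct > pi_threshold).sum())
    return df.head(k), {"n_variation_above": n_var, "n_pi_above": n_pi}


def fit_linear(x, y) -> LinearFit:
    """OLS fit of y on x with R^2 and the two-sided p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return LinearFit(res.slope, res.intercept, res.rvalue**2, res.pvalue)


def subfamily_profiles(
    alignments: dict[str, dict[str, AlignedSet]], min_len: int = 200
) -> pd.DataFrame:
    """Substitutions-only variation% per homologous region per group.

    ``alignments`` maps group -> region name -> alignment; regions shorter
    than ``min_len`` are skipped, absent regions yield missing values.
    """
    regions = sorted({r for d in alignments.values() for r in d})
    out = {}
    for grp, d in alignments.items():
        col = {}
        for r in regions:
            a = d.get(r)
            if a is None or a.length < min_len:
                col[r] = np.nan
            else:
                col[r] = region_variability(a, count_indels=False, name=r).variation_pct
        out[grp] = col
    return pd.DataFrame(out).loc[regions]


# ---------------------------------------------------------------------------
# region extraction


def extract_region_alignments(
    aln: AlignedSet, reference: str, regions: RegionSet | list[Region]
) -> dict[str, AlignedSet]:
    """Slice a whole-genome alignment into per-region alignments.

    Region coordinates are on the ungapped reference sequence; they are mapped
    to alignment columns through the reference row.
    """
    ridx = aln.taxa.index(reference)
    ref_cols = np.nonzero(aln.data[ridx] != GAP)[0]
    out = {}
    for r in regions:
        cols = ref_cols[r.start - 1 : r.end]
        if len(cols) == 0:
            continue
        out[r.name] = aln.slice_columns(slice(int(cols[0]), int(cols[-1]) + 1))
    return out
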