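# Methods

This note records the models, conventions and numerical choices behind
`plastcomp`, in the order of the analysis pipeline. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Genome model and coordinates

Coordinates are 1-based inclusive on every public surface (the GenBank
convention) and 0-based half-open inside functions; conversion happens only
at the boundaries. Circular genomes are analysed linearly in their deposited
rotation; `rotate` re-origins a record and splits origin-spanning features,
flagging them. Ambiguity codes other than the four bases are accepted,
counted as non-GC, and never match anything in downstream comparisons (two
Ns are a mismatch).

Coding percentage is the union coverage of CDS/tRNA/rRNA exon intervals, so
overlapping annotations are not double counted. A gene counts as
"duplicated" when two gene features share a name; when a quadripartite
structure is supplied, both copies must additionally lie wholly inside the
IR arms. Name multiplicity alone is the default because records without a
detectable IR (e.g. partial sequences) still deserve a count.

Region partitioning emits every merged coding exon segment and every gap
between consecutive segments; a gap whose two flanking segments belong to
the same gene is an intron ("*gene* intron"), otherwise a spacer named by
the flanking genes ("trnD(GUC)-psbM"). A length threshold (350 bp for marker
work, 200 bp for cross-group profiles) filters both classes.

## Quadripartite detection

The IR arms are found as the longest pair of disjoint segments where one is
the reverse complement of the other. Any exact common substring of the
sequence and its reverse complement with length ≥ `min_ir` must contain an
aligned k-block (k = `min_ir`/2) of the forward sequence, so block
anchoring with C-speed substring search finds every candidate; matches are
extended maximally in both directions. Arms must be identical by default
(plastid IRs are homogenized copies); a Hamming-tolerant extension mode
(`ir_identity < 1`) exists for degraded genomes. The shorter inter-arm gap
is the SSC. Ties between equal-length candidates break toward the lower
coordinate. The tiling identity |LSC| + |SSC| + 2·|IR| = genome length is
asserted on every detection.

Junction genes are reported per junction with their overhang into the IR; a
junction at the genome end (IRa/LSC in the standard rotation) cannot be
crossed by a linearly represented feature and falls back to
nearest-gene-with-distance, using circular distance.

## Repeat model

A repeat pair is an ungapped alignment of two equal-length segments with
Hamming identity ≥ 0.90 (identity = matches/length, exact rational
arithmetic; ambiguity codes never match). Reported pairs are
**containment-maximal**: a qualifying window is suppressed when a strictly
containing window (same diagonal or nested across diagonals) also
qualifies. This emulates redundancy-filtered maximal-repeat output; one
consequence worth knowing is that a planted exact repeat is usually
reported a few bases longer than planted, extended into the 10% mismatch
budget, and a single substitution inside a repeat can change the reported
length by a base or two between genomes.

Per diagonal, maximal windows are computed exactly: with prefix mismatch
counts c(i) = den·pref(i) − (den−num)·i, a window [a, b] qualifies iff
c(b+1) ≤ c(a), and the containment-maximal set is exactly the record values
of g(a) = max{ j : c(j) ≤ c(a), j ≥ a + min_len }, found with a sorted-index
sweep in O(m log m).

Two code paths share this window computation and agree exactly on their
common domain (asserted in the tests): small inputs (≤ 6 kb total) scan
every diagonal; genome-scale inputs seed diagonals with exact k-mers, k
chosen by pigeonhole so every qualifying minimum-length window must contain
a seed (k = 7 for 30 bp/90%, k = 6 for 20 bp arms), then verify an anchor
condition (some minimum-length window around the seed within the mismatch
budget — for random background this leaves essentially only true repeats)
and run the exact window computation on a padded neighbourhood. Repeat
copies longer than ~1 kb are outside the seeded path's design envelope;
plastome repeats are well under 200 bp.

Tandem arrays are found per unit length u (15–100 bp) from the
adjacent-copy identity predicate, vectorized via the lag-u match profile;
arrays with more than two copies are validated against the column-majority
consensus (each copy ≥ 90%), trimming from the right. Redundant calls
contained in a kept array's interval are dropped, preferring longer spans
and then smaller units.

Whole-genome scans mask one IR arm first so the genome-scale IR does not
flood the repeat list (its arm pair also exceeds the 3 kb palindrome gap
limit by construction). Overlapping same-type motifs merge into one motif
(union of copies); a region carries one repeat type only, tandem taking
priority over dispersed. Motifs whose copies overlap two tRNA genes, or
both members of a known duplicated gene pair (psaA/psaB by default), are
reclassified as "similarity" and excluded from phylogenetic characters.
Location class is coding/noncoding with "both" for class-spanning motifs
(counted in both when tabulated).

**Shared repeats.** Two motifs in different genomes are the same character
iff they have the same type, identical unit length, and identical
annotation context. Context is the set of overlapping gene names per copy,
or the nearest gene when none overlaps — deliberately without
distinguishing overlap from proximity, since a copy 1 bp inside a gene in
one genome and 1 bp outside it in another is the same homologous locus.
Totals count each repeat once per genome in which it occurs. Because the
length criterion is strict, substitutions inside a repeat can split one
ancestral repeat into two characters in diverged genomes; with planted
histories and no divergence the recovery is exact (asserted), and unique
counts stay exact at a tenth of study-scale divergence.

## Parsimony

Fitch tree length is computed per character with bitmask state sets on a
postorder program, vectorized across characters; '?' is always missing, '-'
is missing for DNA matrices (alignment gaps excluded, the study convention)
and a real state for binary matrices. Per character the minimum conceivable
steps are (distinct observed states − 1) and the maximum is
(non-missing taxa − largest state class); CI = m/s and RI = (g − s)/(g − m)
sum both over all characters, uninformative ones included (the classic
program default, needed for comparability with published CI/RI values).

Exhaustive search enumerates all (2n−5)!! unrooted binary topologies by
stepwise addition (hard-capped at nine taxa, 135,135 trees) and returns
every co-optimal topology; a stepwise-addition + NNI heuristic serves
larger matrices and is not part of acceptance. Bootstrap resamples
characters with replacement; each replicate is solved exhaustively and
contributes the bipartitions of the **strict consensus** of its co-optimal
trees, so a split a replicate cannot pin down adds no support. This
convention makes a matrix with a single variable character support exactly
its induced split at 100%. Seeds are mandatory; support vectors are
bit-identical across reruns.

Character mapping roots at the outgroup, takes the outgroup state as
ancestral, and reports origins = Fitch length of the character;
synapomorphic ⇔ one origin (an autapomorphy is a single origin too — the
classification separates single-origin from homoplasious characters, not
clade-defining from private ones).

## Divergence statistics

p-distance uses pairwise deletion: for each pair, columns with a gap or
ambiguity in either row are excluded; the distance is mismatches over
compared sites. Group means are arithmetic means of the relevant pairwise
values, so the overall mean is exactly the pair-count-weighted mean of
within- and between-group values (asserted). Pairs with zero comparable
sites are flagged undefined.

Identity profiles are reference-anchored (columns gapped in the reference
collapse first); identity in a window counts exact unambiguous matches over
the window length, so gaps and Ns count as differences. Defaults: 100 bp
windows, 25 bp step.

Region variability follows the mutation-event proportion
variation% = 100·(NS + ID)/L: NS sums column-level minimal changes
(distinct non-gap states − 1 per column) — the minimal-change reading of
"number of substitutions"; ID counts distinct maximal gap runs, where runs
with identical start and end across taxa collapse to one event, same-start
different-length runs count separately, and a fully gapped row (missing
taxon) contributes nothing. Marker mode counts indels; cross-subfamily
profiles count substitutions only. PI sites are columns with ≥2 states each
carried by ≥2 taxa. Ranking is by descending variation%, ties broken by
PI% then name; the summary reports how many regions exceed 4% variation and
how many of those exceed 3% PI. The PI-vs-variability fit is ordinary least
squares with the two-sided slope p-value.

## Indels and small inversions

Indel coding is simple indel coding: every maximal gap run with identical
boundaries is one candidate binary event. Polarity compares to the outgroup
row: outgroup ungapped ⇒ the gap is a deletion (−) and gapped taxa carry
the derived state; outgroup gapped ⇒ an insertion (+) carried by the
ungapped ingroup taxa. Events invariant across the ingroup are dropped;
autapomorphic events are retained. Coded events append to character
matrices as 0/1 columns and are classified by parsimony mapping on a fixed
reference topology.

Small inversions are anchored by palindromic arm pairs on the ungapped
reference; a taxon carries the inverted orientation of the enclosed segment
when the reverse complement of its segment matches the reference segment at
≥ 0.90 while the direct comparison stays below 0.50 (edit-distance identity
when lengths differ, via edlib). An inverted segment spawns nested arm
pairs, so overlapping calls with the same taxon set collapse to the
outermost. Normalization either drops the inversion columns or
reverse-complements the minority orientation in place; reorientation is
idempotent and strictly lowers the p-distance of the affected pairs.

## Simulator

The generator is the package's test bed: every pipeline stage can be run
against a known truth with no downloads.

**Architecture.** The default layout follows the grass plastome: LSC
83,000 bp, SSC 12,800 bp, IR 21,800 bp (139,400 bp total at scale 1); 131
gene features — 112 unique names (77 protein-coding, 31 tRNA, 4 rRNA) of
which 19 are duplicated in the IR; base composition tuned to 38.9% GC;
gene lengths chosen so coding coverage lands near 50.6%; ndhH crosses the
SSC/IRa junction by 180 nt (the published overhang range is 172–195). All
marker-relevant spacers exist by construction (trnD(GUC)-psbM, ycf4-cemA,
rpl32-trnL(UAG), the rpl16 intron, …). A `scale` parameter shrinks region
and gene lengths while keeping the full gene inventory; a ~7 kb
`toy_architecture` serves fast unit tests. Supported scales with the
default plants are ≥ 0.3.

**Evolution.** Sites are tracked by column identity, which yields an exact
true alignment (leaf id-sequences merge into a global column order; no
realignment) and a truth log whose replay reproduces every leaf
byte-for-byte (asserted). Substitutions are Poisson per branch (JC default,
K2P optional) with per-site weights: exons 0.6, noncoding 1.4, IR 0.5,
normalized to genome-wide mean 1 so branch lengths are expected
substitutions per site; region multipliers (`plant_markers`) re-enter the
normalization, keeping overall divergence calibrated. IR arms evolve
concertedly: substitutions are drawn in IRb only and mirrored
complementarily into IRa, which keeps the arms identical and the effective
per-site rate equal to the branch length; indels are confined to
single-copy regions. The two bases flanking each SSC junction are held
immutable so planted junctions stay crisp and quadripartite detection
recovers the planted intervals exactly. Indels are Poisson with rate 0.08
of the substitution rate, geometric lengths (mean 4 bp), frame-preserving
(multiples of 3) when anchored in exons, and 10-fold rarer in exons than in
noncoding sequence; deletions truncate at region boundaries.

**Planted events.** Repeat gains are duplications: a segment of spacer
sequence is copied and *inserted* (not overwritten) on a chosen branch —
adjacent for tandem, into another spacer for dispersed, reverse-complemented
downstream for palindromic — so repeat birth adds alignment gaps rather
than fake substitution columns and leaves p-distances unbiased. Inversion
loci are pre-planted at the root as palindromic arms around a segment; the
event reverse-complements the segment in place on its branch. These loci
take substitutions but are protected from indels, so orientation rather
than presence is the varying signal.

**Study-scale defaults.** The default eight-taxon tree mirrors the bamboo
sampling (three Bambuseae, five Arundinarieae) with branch lengths chosen
so realized group p-distances land near the published 0.002 (within
Arundinarieae), 0.003 (within Bambuseae), 0.014 (between tribes) and 0.009
overall; the calibration test requires the four realized means to be within
20% of these targets. The default repeat history echoes the published
pattern: a core shared by all taxa, a block on the temperate-clade stem,
unique repeats concentrated in *Bambusa emeiensis* (five), none in
*Phyllostachys edulis*, and a 65 bp tandem unit on the *P. nigra* terminal.
Two inversions are planted in the rpl32-trnL(UAG) and ndhF-rpl32 spacers,
one on the *Phyllostachys* pair stem and one on the *B. emeiensis*
terminal.

`simulate_repeat_matrix` generates binary repeat characters directly on a
tree (gains on internal edges, optional 5% homoplasy) for
topology-recovery experiments without sequence simulation.

## Problem sizes and determinism

The test suite exercises oracle comparisons on ≤ 600 bp fixtures (the
brute-force window oracles are cubic), simulations at scales 0.05–0.5, and
one full pipeline run at scale 0.5; the whole suite runs in under two
minutes on one CPU. The acceptance script runs the full analysis at scale
1.0 (139.7 kb genomes, eight taxa, six-genome repeat comparison, 1000
bootstrap replicates, 100 recovery replicates) in about a minute. All
randomness flows through seeded NumPy generators; identical seeds give
bit-identical outputs everywhere, including bootstrap support vectors and
pipeline tables.

## Known limitations

* The repeat identity model is ungapped; an indel inside a repeat copy
  splits it into two reported pairs rather than one gapped alignment.
* Strict identical-length matching of shared repeats fragments characters
  as divergence grows (see above); a tolerance would trade precision for
  recall and is deliberately not the default.
* The simulator does not model codon structure, base-composition
  heterogeneity, recombination, or IR expansion/contraction; the true
  alignment is maintained event-by-event, so alignment-error effects on
  downstream statistics are out of scope by design.
* Heuristic tree search (n > 9) is stepwise addition + NNI hill climbing —
  adequate for sanity checks, not a replacement for a full TBR search.
* p-distance treats all ambiguity codes as missing rather than partially
  informative.
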