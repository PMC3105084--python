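# plastcomp

Comparative analysis of quadripartite plastomes (chloroplast genomes), built
for the kind of question that drives plastid phylogenomics in slowly evolving
plant groups such as woody bamboos: when whole-genome divergence is tiny
(p-distances of 0.002–0.014), which genomic characters — repeats, indels,
small inversions, rapidly evolving spacers — still carry phylogenetic signal,
and how should they be extracted and scored?

The package implements, as a tested library with a thin CLI:

* **Genome model** — GenBank/FASTA I/O, genome statistics (length, GC%,
  coding fraction as the union of CDS/tRNA/rRNA exons, gene counts with
  IR-duplicates), and partitioning into coding exons, intergenic spacers and
  introns named by their flanking genes.
* **Quadripartite structure** — detection of the two identical inverted
  repeat arms (IRa/IRb) and the large/small single-copy regions, with the
  tiling identity |LSC| + |SSC| + 2·|IR| = genome length and a junction
  report (e.g. the *ndhH* overhang into the IR).
* **Repeat scanning** — dispersed (≥30 bp), tandem (unit ≥15 bp) and
  palindromic (arm ≥20 bp, gap ≤3 kb) repeats at ≥90% ungapped Hamming
  identity, reported as containment-maximal pairs, merged with
  tandem-over-dispersed priority, tRNA/gene-similarity filtering, and
  cross-genome comparison: repeats with the same type, identical length and
  the same homologous-region context are one binary character.
* **Parsimony** — Fitch tree length on arbitrary discrete matrices,
  exhaustive search over all unrooted binary topologies (4–9 taxa; 105 at
  six), CI = m/s and RI = (g − s)/(g − m) with uninformative characters
  included, nonparametric bootstrap, and parsimony mapping of single
  characters (synapomorphic ⇔ one origin).
* **Divergence** — p-distances with pairwise deletion and group means,
  sliding-window identity profiles, per-region variability
  variation% = 100·(NS + ID)/L (column-level substitution events NS, distinct
  indel events ID, aligned length L), parsimony-informative-site fractions,
  marker ranking, and the PI% ~ variable-site% regression.
* **Indels & inversions** — simple indel coding of exon gap runs polarized
  against an outgroup, appending them to character matrices, synapomorphy
  classification on a reference tree, and detection of small inversions
  flanked by palindromic repeats (with exclude/reorient normalization).
* **Simulator** — synthetic plastomes evolving on a known tree with the
  canonical grass architecture (LSC ≈ 83 kb, SSC ≈ 12.8 kb, IR ≈ 21.8 kb,
  131 genes, GC ≈ 38.9%), concerted IR evolution, region-specific rates,
  planted repeats, indels, hot marker regions and inversions — every stage
  of the pipeline is testable against a known truth without any downloads.

## Worked example

Repeat presence/absence characters simulated on a known six-taxon tree,
scored by exhaustive parsimony (`examples/04_repeat_parsimony.py`):

```
matrix: 6 taxa x 41 binary repeat characters
optimal trees: 1
tree length 41 steps, CI 1.000, RI 1.000
recovered the generating topology: True
newick: (Bambusa_emeiensis,Ferrocalamus_rimosivaginus,(Acidosasa_purpurea,
         (Indocalamus_longiauritus,(Phyllostachys_edulis,Phyllostachys_nigra))));
  split {Bamb,Ferr}: 100.0% bootstrap
  split {Indo,Phyl,Phyl}: 100.0% bootstrap
  split {Phyl,Phyl}: 100.0% bootstrap
```

The single most parsimonious tree needs 41 steps — one gain per character, so
CI = 1 (no homoplasy) — and every split has full bootstrap support.

Marker ranking on a study-shaped eight-taxon bundle with three spacers
planted at a 5× elevated mutation rate
(`examples/05_divergence_and_markers.py`):

```
overall mean p-distance: 0.009
top candidate markers (variation%):
             region  length  NS  ID  variation_pct   pi_pct
     trnD(GUC)-psbM     186  26   6      17.204301 6.989247
          ycf4-cemA     171  25   2      15.789474 8.187135
trnG(UCC)-trnT(GGU)     141  18   2      14.184397 6.382979
PI% ~ variable%: slope 0.549, R^2 0.7092, p 1e-23
```

The three rate-elevated spacers occupy the top three ranks, and the fraction
of parsimony-informative sites rises linearly with overall variability.

Each script in `examples/` demonstrates one capability end to end; the
`plastcomp` CLI (`stats`, `structure`, `repeats`, `repeat-tree`, `distance`,
`profile`, `simulate`, `run`) wraps the same library functions for shell use.

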