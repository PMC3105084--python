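"""Parsimony analysis of a repeat presence/absence matrix.

Simulates binary repeat characters born on the branches of a known
six-taxon tree, runs an exhaustive Fitch parsimony search over all 105
unrooted topologies, and reports tree length, consistency and retention
indices, and bootstrap support.  The generating topology should come back
as the unique optimum with high support.
"""
from plastcomp import bootstrap, exhaustive_search
from plastcomp.simulate import SIX_TAXON_TREE, simulate_repeat_matrix

M, truth = simulate_repeat_matrix(SIX_TAXON_TREE, n_informative=30, seed=3)
print(f"matrix: {M.n_taxa} taxa x {M.n_chars} binary repeat characters")

optima, score = exhaustive_search(M)
best = optima[0]
print(f"optimal trees: {len(optima)}")
print(f"tree length {score.s} steps, CI {score.ci:.3f}, RI {score.ri:.3f}")
print("recovered the generating topology:", best == truth)
print("newick:", best.newick(outgroup="Bambusa_emeiensis"))

support = bootstrap(M, reps=500, seed=5)
for bip in sorted(best.bipartitions(), key=sorted):
    print(f"  split {{{','.join(sorted(t.split('_')[0][:4] for t in bip))}}}: "
          f"{support.get(bip, 0.0):.1f}% bootstrap")
print(
    "\nCI close to 1 means the characters are nearly homoplasy-free; every "
    "split of the generating tree should be strongly supported."
)
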