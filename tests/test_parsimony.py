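import numpy as np
import pytest

from plastcomp.parsimony import (
    CharacterMatrix,
    Topology,
    bootstrap,
    enumerate_topologies,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    map_character,
    n_unrooted_topologies,
    read_nexus,
    score_stats,
    strict_consensus,
    write_nexus,
)
from oracles import fitch_by_enumeration, matrix_length_by_enumeration


def random_binary_matrix(rng, taxa, n_chars):
    rows = ["".join(rng.choice(["0", "1"], size=n_chars)) for _ in taxa]
    return CharacterMatrix(list(taxa), rows)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105), (7, 945)])
    def test_topology_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        topos = list(enumerate_topologies(taxa))
        assert len(topos) == count == n_unrooted_topologies(n)
        # all distinct as unrooted shapes
        assert len(set(topos)) == count


class TestFitch:
    def test_constant_character_is_free(self):
        M = CharacterMatrix(list("ABCD"), ["1", "1", "1", "1"])
        for t in enumerate_topologies(list("ABCD")):
            assert fitch_length(t, M) == 0

    def test_four_taxon_single_step(self):
        M = CharacterMatrix(list("ABCD"), ["1", "1", "0", "0"])
        t = Topology.from_newick("((A,B),(C,D));", taxa=list("ABCD"))
        assert fitch_length(t, M) == 1
        t2 = Topology.from_newick("((A,C),(B,D));", taxa=list("ABCD"))
        assert fitch_length(t2, M) == 2

    def test_missing_state_is_wildcard(self):
        M = CharacterMatrix(list("ABCD"), ["1", "?", "0", "0"])
        t = Topology.from_newick("((A,B),(C,D));", taxa=list("ABCD"))
        assert fitch_length(t, M) == 1

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_labeling_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        taxa = [f"t{i}" for i in range(n)]
        for rep in range(3):
            M = random_binary_matrix(rng, taxa, 6)
            for t in list(enumerate_topologies(taxa))[:: max(1, n - 2)]:
                assert fitch_length(t, M) == matrix_length_by_enumeration(t, M)

    def test_invariant_to_rerooting_and_taxon_order(self):
        rng = np.random.default_rng(0)
        taxa = list("ABCDEF")
        M = random_binary_matrix(rng, taxa, 12)
        t = Topology.from_newick("((A,B),(C,(D,(E,F))));", taxa=taxa)
        base = fitch_length(t, M)
        for nwk in ("((C,(D,(E,F))),(A,B));", "(D,(E,F),(C,(B,A)));"):
            assert fitch_length(Topology.from_newick(nwk, taxa=taxa), M) == base
        # row order of the matrix is irrelevant
        M2 = M.subset(list(reversed(taxa)))
        assert fitch_length(t, M2) == base

    def test_taxon_mismatch_raises(self):
        M = CharacterMatrix(list("ABC"), ["0", "1", "0"])
        t = Topology.from_newick("((A,B),(C,D));", taxa=list("ABCD"))
        with pytest.raises(ValueError):
            fitch_length(t, M)


class TestScoreStats:
    def test_homoplasy_free_matrix_has_ci_one(self):
        taxa = list("ABCDEF")
        t = Topology.from_newick("((A,B),(C,(D,(E,F))));", taxa=taxa)
        M = CharacterMatrix(taxa, ["10", "10", "00", "00", "01", "01"])
        s = score_stats(t, M)
        assert s.ci == 1.0 and s.m <= s.s <= s.g

    def test_g_equals_bruteforce_max_over_topologies(self):
        # binary character with 3 ones / 3 zeros on 6 taxa -> g = 3
        taxa = list("ABCDEF")
        M = CharacterMatrix(taxa, ["1", "1", "1", "0", "0", "0"])
        lengths = [fitch_length(t, M) for t in enumerate_topologies(taxa)]
        assert max(lengths) == 3
        s = score_stats(next(iter(enumerate_topologies(taxa))), M)
        assert s.g == 3

    def test_bounds_hold_on_random_matrices(self):
        rng = np.random.default_rng(7)
        taxa = list("ABCDE")
        for _ in range(5):
            M = random_binary_matrix(rng, taxa, 8)
            for t in list(enumerate_topologies(taxa))[::3]:
                s = score_stats(t, M)
                assert s.m <= s.s <= s.g


class TestSearch:
    def test_exhaustive_matches_independent_scoring(self):
        rng = np.random.default_rng(3)
        taxa = list("ABCDEF")
        M = random_binary_matrix(rng, taxa, 7)
        opts, score = exhaustive_search(M)
        oracle_best = min(
            matrix_length_by_enumeration(t, M) for t in enumerate_topologies(taxa)
        )
        assert score.s == oracle_best
        for t in opts:
            assert matrix_length_by_enumeration(t, M) == oracle_best

    def test_all_constant_matrix_ties_all_topologies(self):
        taxa = list("ABCDEF")
        M = CharacterMatrix(taxa, ["10"] * 6)
        opts, score = exhaustive_search(M)
        assert len(opts) == 105 and score.s == 0
        assert strict_consensus(opts) == frozenset()

    def test_out_of_range_taxa_raise(self):
        M = CharacterMatrix(list("ABC"), ["0", "1", "0"])
        with pytest.raises(ValueError):
            exhaustive_search(M)

    def test_heuristic_agrees_with_exhaustive_on_small_matrix(self):
        rng = np.random.default_rng(5)
        taxa = list("ABCDEFG")
        M = random_binary_matrix(rng, taxa, 20)
        opts, score = exhaustive_search(M)
        t, ln = heuristic_search(M, seed=1, n_starts=3)
        assert ln == score.s


class TestBootstrap:
    def test_single_variable_character(self):
        taxa = list("ABCDEF")
        M = CharacterMatrix(taxa, ["1", "1", "0", "0", "0", "0"])
        sup = bootstrap(M, reps=50, seed=9)
        induced = frozenset({"A", "B"})
        # the induced split is the only one ever supported
        informative = {b: v for b, v in sup.items() if v > 0}
        assert set(informative) <= {induced, frozenset({"C", "D", "E", "F"})}

    def test_fixed_seed_is_bit_identical(self):
        rng = np.random.default_rng(11)
        M = random_binary_matrix(rng, list("ABCDEF"), 15)
        assert bootstrap(M, reps=30, seed=4) == bootstrap(M, reps=30, seed=4)


class TestMapCharacter:
    TAXA = ["O", "A", "B", "C", "D", "E"]
    TREE = Topology.from_newick("(O,(A,(B,(C,(D,E)))));", taxa=TAXA)

    def test_clade_confined_state_is_synapomorphic(self):
        states = {"O": "0", "A": "0", "B": "0", "C": "0", "D": "1", "E": "1"}
        fate = map_character(self.TREE, states, outgroup="O")
        assert fate.origins == 1 and fate.classification == "synapomorphic"
        assert set(fate.derived_taxa) == {"D", "E"}

    def test_disjoint_clades_need_two_origins(self):
        states = {"O": "0", "A": "1", "B": "0", "C": "0", "D": "1", "E": "1"}
        fate = map_character(self.TREE, states, outgroup="O")
        assert fate.origins == 2 and fate.classification == "homoplasious"
        # cross-check with the labeling enumeration oracle
        col = [states[t] for t in self.TREE.taxa]
        oracle = fitch_by_enumeration(
            self.TREE.edges, 6, [frozenset([c]) for c in col]
        )
        assert fate.origins == oracle

    def test_missing_outgroup_state_flagged(self):
        states = {"O": "?", "A": "1", "B": "0", "C": "0", "D": "0", "E": "0"}
        fate = map_character(self.TREE, states, outgroup="O")
        assert fate.polarity_flagged


class TestIO:
    def test_nexus_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        M = random_binary_matrix(rng, ["tax_a", "tax_b", "tax_c", "tax_d"], 9)
        p = tmp_path / "m.nex"
        write_nexus(M, p)
        back = read_nexus(p)
        assert back.taxa == M.taxa and back.rows == M.rows

    def test_newick_round_trip_preserves_splits(self):
        taxa = list("ABCDEF")
        t = Topology.from_newick("((A,B),(C,(D,(E,F))));", taxa=taxa)
        back = Topology.from_newick(t.newick(), taxa=taxa)
        assert back == t
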