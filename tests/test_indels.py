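import numpy as np
import pytest

from plastcomp.divergence import AlignedSet, p_distance
from plastcomp.indels import (
    classify_events,
    code_and_append,
    detect_small_inversions,
    extract_exon_indels,
    normalize_inversions,
)
from plastcomp.parsimony import CharacterMatrix, Topology, fitch_length
from conftest import random_seq
from oracles import revcomp


def aln(rows):
    return AlignedSet.from_dict(rows)


class TestExtractIndels:
    BASE = "ATGGCTGCTAAAGCTGCTGGTTGA"  # 24 bp toy exon

    def test_deletion_polarity_and_bearers(self):
        gapped = self.BASE[:6] + "------" + self.BASE[12:]
        rows = {"OUT": self.BASE, "A": gapped, "B": gapped, "C": self.BASE}
        events = extract_exon_indels({"g1": aln(rows)}, outgroup="OUT")
        (ev,) = events
        assert ev.size == 6 and ev.polarity == "-"
        assert set(ev.derived_taxa) == {"A", "B"}

    def test_insertion_when_outgroup_shares_gap(self):
        gapped = self.BASE[:6] + "------" + self.BASE[12:]
        rows = {"OUT": gapped, "A": gapped, "B": self.BASE, "C": self.BASE}
        (ev,) = extract_exon_indels({"g1": aln(rows)}, outgroup="OUT")
        assert ev.polarity == "+"
        assert set(ev.derived_taxa) == {"B", "C"}

    def test_polarity_flips_with_outgroup_state(self):
        gapped = self.BASE[:3] + "---" + self.BASE[6:]
        for og_row, pol in ((self.BASE, "-"), (gapped, "+")):
            rows = {"OUT": og_row, "A": gapped, "B": self.BASE}
            (ev,) = extract_exon_indels({"g": aln(rows)}, outgroup="OUT")
            assert ev.polarity == pol

    def test_ingroup_invariant_events_dropped(self):
        gapped = self.BASE[:6] + "---" + self.BASE[9:]
        rows = {"OUT": self.BASE, "A": gapped, "B": gapped}
        assert extract_exon_indels({"g": aln(rows)}, outgroup="OUT") == []

    def test_missing_outgroup_raises(self):
        rows = {"A": self.BASE, "B": self.BASE}
        with pytest.raises(ValueError):
            extract_exon_indels({"g": aln(rows)}, outgroup="OUT")


class TestCodingAndClassification:
    TAXA = ["O", "A", "B", "C", "D"]
    TREE = Topology.from_newick("(O,(A,(B,(C,D))));", taxa=TAXA)

    def _event(self, derived):
        from plastcomp.indels import IndelEvent

        return IndelEvent("g", 1, 3, "-", tuple(derived))

    def test_constant_character_leaves_tree_length_unchanged(self):
        M = CharacterMatrix(self.TAXA, ["ACGT", "ACGA", "ACTA", "AGTA", "AGTA"], kind="dna")
        base = fitch_length(self.TREE, M)
        M2 = code_and_append([self._event(["A", "B", "C", "D"])], M)
        # derived everywhere in the ingroup: outgroup 0, one step added
        M3 = code_and_append([], M)
        assert fitch_length(self.TREE, M3) == base

    def test_appended_events_add_their_fitch_steps(self):
        M = CharacterMatrix(self.TAXA, ["A", "A", "A", "A", "A"], kind="dna")
        events = [self._event(["C", "D"]), self._event(["A", "C"])]
        M2 = code_and_append(events, M)
        assert M2.n_chars == 3
        # (C,D) clade: 1 step; (A,C) disjoint: 2 steps
        assert fitch_length(self.TREE, M2, gaps_missing=False) == 3

    def test_classification_partition(self):
        events = [self._event(["C", "D"]), self._event(["A", "C"]), self._event(["B"])]
        out = classify_events(events, self.TREE, "O")
        syn = [e for e in out if e.classification == "synapomorphic"]
        hom = [e for e in out if e.classification == "homoplasious"]
        assert len(syn) + len(hom) == len(events)
        assert [e.origins for e in out] == [1, 2, 1]


class TestInversions:
    def _planted(self, rng, n_flank=150, arm=22, seg=30):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        while True:  # forbid chance extension of the planted arms
            arm_s = random_seq(rng, arm)
            seg_s = random_seq(rng, seg)
            left, right = random_seq(rng, n_flank), random_seq(rng, n_flank)
            if seg_s[0] != comp[seg_s[-1]] and left[-1] != comp[right[0]]:
                break
        ref = left + arm_s + seg_s + revcomp(arm_s) + right
        inv = left + arm_s + revcomp(seg_s) + revcomp(arm_s) + right
        return ref, inv, (n_flank + arm + 1, n_flank + arm + seg)

    def test_planted_inversion_detected_with_exact_coordinates(self, rng):
        ref, inv, seg = self._planted(rng)
        a = aln({"R": ref, "Q": inv, "S": ref})
        events = detect_small_inversions(
            a, "R", min_arm=15, max_gap=200, min_identity=1.0
        )
        (ev,) = events
        assert ev.taxa == ("Q",)
        assert ev.segment == seg

    def test_no_inversion_gives_empty_list(self, rng):
        ref, _, _ = self._planted(rng)
        a = aln({"R": ref, "Q": ref})
        assert detect_small_inversions(a, "R", min_arm=15, max_gap=200) == []

    def test_exclude_mode_drops_segment_columns(self, rng):
        ref, inv, seg = self._planted(rng)
        a = aln({"R": ref, "Q": inv})
        events = detect_small_inversions(a, "R", min_arm=15, max_gap=200)
        out = normalize_inversions(a, events, mode="exclude", reference="R")
        dropped = sum(e.segment[1] - e.segment[0] + 1 for e in events)
        assert out.length == a.length - dropped

    def test_reorient_mode_decreases_p_distance_and_is_idempotent(self, rng):
        ref, inv, _ = self._planted(rng)
        a = aln({"R": ref, "Q": inv})
        events = detect_small_inversions(a, "R", min_arm=15, max_gap=200)
        fixed = normalize_inversions(a, events, mode="reorient", reference="R")
        before = p_distance(a).matrix.loc["R", "Q"]
        after = p_distance(fixed).matrix.loc["R", "Q"]
        assert after < before
        assert detect_small_inversions(fixed, "R", min_arm=15, max_gap=200) == []
        again = normalize_inversions(fixed, [], mode="reorient", reference="R")
        assert np.array_equal(again.data, fixed.data)

    def test_simulated_inversions_recovered(self, bamboo_sim):
        events = detect_small_inversions(
            bamboo_sim.alignment, reference="Acidosasa_purpurea"
        )
        by_taxa = {frozenset(e.taxa) for e in events}
        assert frozenset({"Phyllostachys_edulis", "Phyllostachys_nigra"}) in by_taxa
        assert frozenset({"Bambusa_emeiensis"}) in by_taxa
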