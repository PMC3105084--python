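import numpy as np
import pytest

from plastcomp.genome import Feature, GenomeRecord
from plastcomp.repeats import (
    find_dispersed,
    find_palindromic,
    find_tandem,
    resolve_and_classify,
    shared_repeats,
    to_binary_matrix,
)
from conftest import random_seq
from oracles import (
    brute_dispersed,
    brute_palindromic,
    brute_tandem_intervals,
    revcomp,
)


def motif_pairs(motifs):
    """Normalize 2-copy motifs to 0-based (i, j, L) triples."""
    out = set()
    for m in motifs:
        (s1, e1, _), (s2, e2, _) = sorted(m.copies)[:2]
        out.add((s1 - 1, s2 - 1, e1 - s1 + 1))
    return sorted(out)


class TestDispersedOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_quadratic_oracle_on_random(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 160)
        got = motif_pairs(find_dispersed(seq, min_len=12, min_identity=0.9))
        assert got == brute_dispersed(seq, min_len=12, min_identity=0.9)

    def test_agrees_with_oracle_on_planted_duplication(self, rng):
        seq = random_seq(rng, 180)
        unit = random_seq(rng, 25)
        seq = seq[:30] + unit + seq[55:120] + unit + seq[145:]
        got = motif_pairs(find_dispersed(seq, min_len=20, min_identity=0.9))
        assert got == brute_dispersed(seq, min_len=20, min_identity=0.9)
        assert len(got) >= 1

    def test_exact_planted_pair_in_500bp(self, rng):
        seq = random_seq(rng, 500)
        unit = random_seq(rng, 40)
        seq = seq[:100] + unit + seq[140:300] + unit + seq[340:]
        motifs = find_dispersed(seq, min_len=30, min_identity=0.9)
        assert any(
            s1 - 1 <= 100 and e1 >= 140 for (s1, e1, _), _ in (m.copies for m in motifs)
        )
        # and full agreement with the oracle
        assert motif_pairs(motifs) == brute_dispersed(seq)

    def test_short_sequence_empty(self):
        assert find_dispersed("ACGT", min_len=30) == []

    def test_seeded_path_matches_exhaustive_path(self, rng):
        """The genome-scale seeded scan and the small-input exhaustive scan
        must report the same repeats on the same sequence."""
        from plastcomp import _matchengine as me

        seq = random_seq(rng, 2000)
        unit = random_seq(rng, 45)
        seq = seq[:300] + unit + seq[345:1500] + unit + seq[1545:]
        exact = me.scan_pairs(seq, None, min_len=30, min_identity=0.9)
        old = me.SMALL_INPUT
        try:
            me.SMALL_INPUT = 0  # force the seeded path
            seeded = me.scan_pairs(seq, None, min_len=30, min_identity=0.9)
        finally:
            me.SMALL_INPUT = old
        assert exact == seeded and len(exact) >= 1


class TestPalindromicOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 130)
        got = motif_pairs(find_palindromic(seq, min_arm=10, max_gap=60, min_identity=0.9))
        assert got == brute_palindromic(seq, min_arm=10, max_gap=60, min_identity=0.9)

    def test_perfect_hairpin_detected(self, rng):
        arm = random_seq(rng, 30)
        seq = random_seq(rng, 150) + arm + random_seq(rng, 100) + revcomp(arm) + random_seq(rng, 150)
        # exact-identity mode reports the planted arms verbatim
        exact = find_palindromic(seq, min_arm=20, max_gap=3000, min_identity=1.0)
        assert any(
            m.identity == 1.0 and m.copies[0][0] <= 151 and m.unit_length >= 30
            for m in exact
        )
        # the default 90% mode may absorb the arms into a wider maximal
        # window; it must still agree exactly with the brute-force oracle
        motifs = find_palindromic(seq, min_arm=20, max_gap=3000)
        assert motif_pairs(motifs) == brute_palindromic(seq, min_arm=20, max_gap=3000)
        assert any(m.identity >= 0.9 for m in motifs)

    def test_gap_limit_excludes_distant_arms(self, rng):
        arm = random_seq(rng, 25)
        seq = arm + random_seq(rng, 500) + revcomp(arm)
        assert find_palindromic(seq, min_arm=20, max_gap=100) == []
        assert len(find_palindromic(seq, min_arm=20, max_gap=600)) == 1


class TestTandem:
    def test_short_units_not_reported(self):
        assert find_tandem("ACGT" * 3, min_unit=15) == []

    def test_planted_unit_with_one_mismatch(self, rng):
        unit = random_seq(rng, 20)
        copy2 = unit[:10] + ("A" if unit[10] != "A" else "C") + unit[11:]
        seq = random_seq(rng, 60) + unit + copy2 + unit + random_seq(rng, 60)
        motifs = find_tandem(seq, min_unit=15, min_identity=0.9)
        best = max(motifs, key=lambda m: len(m.copies))
        assert len(best.copies) == 3 and best.unit_length == 20
        assert best.identity >= 0.95

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coverage_agrees_with_period_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 120)
        unit = random_seq(rng, 16)
        seq = seq[:40] + unit * 3 + seq[88:]
        got = set()
        for m in find_tandem(seq, min_unit=12, min_identity=0.9, max_unit=40):
            s, e = m.interval
            got.update(range(s - 1, e))
        oracle = brute_tandem_intervals(seq, min_unit=12, min_identity=0.9, max_unit=40)
        assert got == oracle


class TestStrandInvariance:
    def test_repertoire_maps_onto_reverse_complement(self, rng):
        seq = random_seq(rng, 400)
        unit = random_seq(rng, 35)
        arm = random_seq(rng, 22)
        seq = (seq[:50] + unit + seq[85:150] + unit + seq[185:260]
               + arm + seq[282:330] + revcomp(arm) + seq[352:])
        n = len(seq)

        def canon(motifs):
            return sorted(
                (m.type, m.unit_length, round(m.identity, 6)) for m in motifs
            )

        fwd = find_dispersed(seq) + find_palindromic(seq, max_gap=n)
        rev = find_dispersed(revcomp(seq)) + find_palindromic(revcomp(seq), max_gap=n)
        assert canon(fwd) == canon(rev)


class TestResolveClassify:
    def _record(self, seq, feats=()):
        return GenomeRecord("G1", seq, features=list(feats))

    def test_tandem_priority_over_dispersed(self, rng):
        unit = random_seq(rng, 20)
        seq = random_seq(rng, 100) + unit * 4 + random_seq(rng, 100)
        rec = self._record(seq)
        disp = find_dispersed(seq, min_len=30)
        tand = find_tandem(seq, min_unit=15)
        rs = resolve_and_classify(disp, tand, [], rec)
        kinds = {m.type for m in rs}
        assert "tandem" in kinds and "dispersed" not in kinds

    def test_trna_similarity_reclassified_and_excluded(self, rng):
        unit = random_seq(rng, 40)
        seq = random_seq(rng, 60) + unit + random_seq(rng, 120) + unit + random_seq(rng, 60)
        feats = [
            Feature("gene", "trnfM(CAU)", [(61, 100, 1)]),
            Feature("tRNA", "trnfM(CAU)", [(61, 100, 1)]),
            Feature("gene", "trnM(CAU)", [(221, 260, 1)]),
            Feature("tRNA", "trnM(CAU)", [(221, 260, 1)]),
        ]
        rec = self._record(seq, feats)
        rs = resolve_and_classify(find_dispersed(seq), [], [], rec)
        assert all(m.type == "similarity" for m in rs)
        other = GenomeRecord("G2", seq, features=feats)
        rs2 = resolve_and_classify(find_dispersed(seq), [], [], other)
        M = to_binary_matrix([rs, rs2])
        assert M.n_chars == 0  # similarity repeats never become characters

    def test_cross_genome_mixing_rejected(self, rng):
        seq = random_seq(rng, 200)
        rec = self._record(seq)
        motifs = find_dispersed(seq, min_len=10, min_identity=0.9)
        tagged = [m.__class__(**{**m.__dict__, "genome_id": "other"}) for m in motifs]
        if tagged:
            with pytest.raises(ValueError):
                resolve_and_classify(tagged, [], [], rec)


class TestSharedRepeats:
    def test_identical_genomes_share_everything(self, rng):
        unit = random_seq(rng, 35)
        seq = random_seq(rng, 80) + unit + random_seq(rng, 150) + unit + random_seq(rng, 80)
        r1 = resolve_and_classify(find_dispersed(seq), [], [], GenomeRecord("A", seq))
        r2 = resolve_and_classify(find_dispersed(seq), [], [], GenomeRecord("B", seq))
        table = shared_repeats([r1, r2])
        assert table.unique == {"A": 0, "B": 0}
        assert table.shared_by(["A", "B"]) == len(r1.non_similarity())

    def test_binary_matrix_states_and_presence(self, rng):
        unit = random_seq(rng, 35)
        seq1 = random_seq(rng, 80) + unit + random_seq(rng, 150) + unit + random_seq(rng, 80)
        seq2 = random_seq(rng, len(seq1))
        r1 = resolve_and_classify(find_dispersed(seq1), [], [], GenomeRecord("A", seq1))
        r2 = resolve_and_classify(find_dispersed(seq2), [], [], GenomeRecord("B", seq2))
        M = to_binary_matrix([r1, r2])
        assert set("".join(M.rows)) <= {"0", "1"}
        assert all("1" in col for col in zip(*M.rows))  # every character present somewhere


class TestSimulatedHistory:
    def test_counts_match_planted_history_without_divergence(self):
        """With zero-length branches the genomes differ only by the planted
        repeat gains, so shared/unique counts equal the planted history."""
        import re
        from dataclasses import replace
        from plastcomp.simulate import bamboo_like_config, simulate
        from plastcomp.quadripartite import detect_quadripartite
        from plastcomp.repeats import scan_genome

        cfg = bamboo_like_config(scale=0.3)
        cfg = replace(cfg, tree=re.sub(r":\d+\.\d+", ":0.0", cfg.tree))
        res = simulate(cfg, seed=5)
        sets = []
        for rec in res.records.values():
            q = detect_quadripartite(rec.seq, min_ir=3000)
            sets.append(scan_genome(rec, q))
        table = shared_repeats(sets)
        planted_unique = {
            "Bambusa_emeiensis": 5, "Bambusa_oldhamii": 1,
            "Dendrocalamus_latiflorus": 1, "Ferrocalamus_rimosivaginus": 2,
            "Acidosasa_purpurea": 1, "Indocalamus_longiauritus": 1,
            "Phyllostachys_edulis": 0, "Phyllostachys_nigra": 1,
        }
        assert table.unique == planted_unique
        arund = ["Ferrocalamus_rimosivaginus", "Acidosasa_purpurea",
                 "Indocalamus_longiauritus", "Phyllostachys_edulis",
                 "Phyllostachys_nigra"]
        # clade-level plants: 4 on the temperate stem, 2 on each nested clade
        assert table.shared_by(arund) == 4
        assert table.shared_by(arund[1:]) == 2  # Arundinaria core
        assert table.shared_by(["Phyllostachys_edulis", "Phyllostachys_nigra"]) == 2
        assert table.shared_by(["Bambusa_oldhamii", "Dendrocalamus_latiflorus"]) == 1
        # 6 root plants + the 2 planted inversion arm pairs, all in every taxon
        assert table.shared_by(res.records.keys()) >= 8

    def test_low_divergence_unique_counts_still_recovered(self):
        """At a tenth of the study-scale divergence, per-taxon unique repeat
        counts still equal the planted terminal gains."""
        from dataclasses import replace
        from plastcomp.simulate import bamboo_like_config, simulate
        from plastcomp.quadripartite import detect_quadripartite
        from plastcomp.repeats import scan_genome

        cfg = bamboo_like_config(scale=0.3)
        cfg = replace(cfg, tree=cfg.tree.replace("0.00", "0.000"))
        res = simulate(cfg, seed=5)
        sets = []
        for rec in res.records.values():
            q = detect_quadripartite(rec.seq, min_ir=3000)
            sets.append(scan_genome(rec, q))
        table = shared_repeats(sets)
        assert table.unique == {
            "Bambusa_emeiensis": 5, "Bambusa_oldhamii": 1,
            "Dendrocalamus_latiflorus": 1, "Ferrocalamus_rimosivaginus": 2,
            "Acidosasa_purpurea": 1, "Indocalamus_longiauritus": 1,
            "Phyllostachys_edulis": 0, "Phyllostachys_nigra": 1,
        }
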