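import numpy as np
import pytest

from plastcomp.divergence import (
    AlignedSet,
    extract_region_alignments,
    fit_linear,
    identity_profile,
    p_distance,
    rank_markers,
    region_variability,
    subfamily_profiles,
)
from plastcomp.genome import Region
from oracles import ols_normal_equations


def aln_from(rows: dict) -> AlignedSet:
    return AlignedSet.from_dict(rows)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        a = aln_from({"x": "ACGTACGT", "y": "ACGTACGT"})
        assert p_distance(a).matrix.loc["x", "y"] == 0.0

    def test_pairwise_deletion_hand_count(self):
        # 10 columns, 1 mismatch, 2 gap columns -> 1/8
        a = aln_from({"x": "ACGTACGTAC", "y": "ACGTACGTA-"})
        rows = {"x": "ACGTACGTAC", "y": "ACCTAC-TA-"}
        a = aln_from(rows)
        d = p_distance(a).matrix.loc["x", "y"]
        assert d == pytest.approx(1 / 8)

    def test_ambiguity_excluded_like_gaps(self):
        a = aln_from({"x": "ACGTN", "y": "ACGAN"})
        assert p_distance(a).matrix.loc["x", "y"] == pytest.approx(1 / 4)

    def test_zero_comparable_sites_flagged(self):
        a = aln_from({"x": "AC--", "y": "--GT"})
        s = p_distance(a)
        assert np.isnan(s.matrix.loc["x", "y"])
        assert ("x", "y") in s.undefined_pairs

    def test_invariant_to_row_and_column_permutation(self, rng):
        n, L = 5, 60
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT-"), size=L)) for i in range(n)
        }
        a = aln_from(rows)
        base = p_distance(a).matrix
        order = list(rows)[::-1]
        shuffled = p_distance(a.subset(order)).matrix.loc[list(rows), list(rows)]
        assert np.allclose(base.values, shuffled.values, equal_nan=True)
        perm = rng.permutation(L)
        a2 = a.slice_columns(perm)
        assert np.allclose(base.values, p_distance(a2).matrix.values, equal_nan=True)

    def test_overall_mean_is_weighted_group_mean(self, rng):
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=80)) for i in range(6)
        }
        groups = {f"t{i}": ("G1" if i < 3 else "G2") for i in range(6)}
        s = p_distance(aln_from(rows), groups=groups)
        n_w1 = n_w2 = 3  # pairs within each group of 3
        n_b = 9
        expected = (
            n_w1 * s.within["G1"] + n_w2 * s.within["G2"] + n_b * s.between[("G1", "G2")]
        ) / (n_w1 + n_w2 + n_b)
        assert s.overall_mean == pytest.approx(expected, abs=1e-12)


class TestIdentityProfile:
    def test_identical_pair_is_hundred_everywhere(self):
        a = aln_from({"r": "ACGT" * 50, "q": "ACGT" * 50})
        prof = identity_profile(a, "r", window=50, step=25)
        assert (prof["q"] == 100.0).all()

    def test_mismatch_block_window_identity(self, rng):
        L, w = 300, 100
        base = "".join(rng.choice(list("ACGT"), size=L))
        other = list(base)
        for i in range(100, 110):  # 10 mismatches inside one window
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
        a = aln_from({"r": base, "q": "".join(other)})
        prof = identity_profile(a, "r", window=w, step=w)
        assert prof["q"].loc[101] == pytest.approx(100 * (w - 10) / w)

    def test_reference_anchored_coordinates(self):
        a = aln_from({"r": "AC--GT", "q": "ACTAGT"})
        prof = identity_profile(a, "r", window=4, step=4)
        # reference collapses to ACGT; q matches everywhere on those columns
        assert prof["q"].loc[1] == 100.0

    def test_window_longer_than_alignment_truncates(self):
        a = aln_from({"r": "ACGTACGT", "q": "ACGTACGA"})
        prof = identity_profile(a, "r", window=100, step=25)
        assert len(prof) == 1
        assert prof["q"].iloc[0] == pytest.approx(100 * 7 / 8)


class TestRegionVariability:
    def test_direct_formula(self):
        # L=100, NS=3, ID=1 -> 4.0%
        base = "A" * 100
        r2 = "C" + base[1:]
        r3 = "AG" + base[2:]
        r4 = base[:50] + "T" + base[51:]
        r5 = base[:80] + "-----" + base[85:]
        a = aln_from({"a": base, "b": r2, "c": r3, "d": r4, "e": r5})
        s = region_variability(a, count_indels=True)
        assert s.length == 100 and s.ns == 3 and s.indels == 1
        assert s.variation_pct == pytest.approx(4.0)

    def test_shared_gap_run_is_one_event(self):
        base = "ACGTACGTACGTACGTACGT"
        gapped = base[:5] + "-----" + base[10:]
        a = aln_from({"a": base, "b": gapped, "c": gapped, "d": base})
        s = region_variability(a)
        assert s.indels == 1

    def test_same_start_different_length_runs_count_separately(self):
        base = "ACGTACGTACGTACGTACGT"
        g1 = base[:5] + "-----" + base[10:]  # run (5, 9)
        g2 = base[:5] + "---" + base[5:8] + base[11:]  # run (5, 7), same length
        s = region_variability(aln_from({"a": base, "b": g1, "c": g2}))
        assert s.indels == 2

    def test_marker_mode_at_least_substitution_mode(self, rng):
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT-"), size=120, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            for i in range(5)
        }
        a = aln_from(rows)
        with_id = region_variability(a, count_indels=True).variation_pct
        without = region_variability(a, count_indels=False).variation_pct
        assert with_id >= without

    def test_pi_sites_definition(self):
        a = aln_from({"a": "AAC", "b": "AAC", "c": "AGT", "d": "AGT"})
        s = region_variability(a)
        # col1 constant; col2 two states x two taxa each (PI); col3 PI too
        assert s.variable_sites == 2 and s.pi_sites == 2

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            region_variability(AlignedSet(["a", "b"], np.zeros((2, 0), dtype=np.uint8)))


class TestRanking:
    def test_single_region_ranks_first(self):
        from plastcomp.divergence import RegionStats

        s = RegionStats("only", "noncoding", 100, 3, 1, 4, 2, 4.0, 2.0)
        df, counts = rank_markers([s])
        assert df.region.tolist() == ["only"]

    def test_ordering_and_threshold_counts(self):
        from plastcomp.divergence import RegionStats

        mk = lambda nm, v, p: RegionStats(nm, "noncoding", 100, 0, 0, 0, int(p), v, p)
        stats = [mk("a", 5.0, 3.5), mk("b", 6.0, 1.0), mk("c", 5.0, 4.0), mk("d", 2.0, 9.9)]
        df, counts = rank_markers(stats)
        assert df.region.tolist() == ["b", "c", "a", "d"]
        assert counts == {"n_variation_above": 3, "n_pi_above": 2}


class TestRegression:
    def test_collinear_points(self):
        fit = fit_linear([1, 2, 3, 4], [2, 4, 6, 8])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.normal(size=10)
        y = 1.3 * x + 0.4 + rng.normal(scale=0.3, size=10)
        fit = fit_linear(x, y)
        slope, intercept, r2 = ols_normal_equations(list(x), list(y))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r_squared_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(scale=0.5, size=12)
        base = fit_linear(x, y).r_squared
        scaled = fit_linear(3.0 * x + 7.0, -2.0 * y + 1.0).r_squared
        assert base == pytest.approx(scaled, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_linear([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])


class TestSubfamilyProfiles:
    def test_identical_alignments_identical_columns(self, rng):
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=250)) for i in range(4)
        }
        a = aln_from(rows)
        table = subfamily_profiles({"G1": {"r": a}, "G2": {"r": a}}, min_len=200)
        assert table.loc["r", "G1"] == table.loc["r", "G2"]

    def test_missing_and_short_regions_are_nan(self, rng):
        rows = {f"t{i}": "".join(rng.choice(list("ACGT"), size=250)) for i in range(3)}
        short = {k: v[:100] for k, v in rows.items()}
        table = subfamily_profiles(
            {"G1": {"r": aln_from(rows)}, "G2": {"s": aln_from(short)}}, min_len=200
        )
        assert np.isnan(table.loc["r", "G2"]) and np.isnan(table.loc["s", "G2"])


class TestRegionExtraction:
    def test_reference_anchored_slicing(self):
        #           123  456789  (reference coordinates)
        rows = {"r": "ACG--TACGTA", "q": "ACGTTTACGTA"}
        a = aln_from(rows)
        regions = [Region("mid", "noncoding", 4, 7, "r")]
        out = extract_region_alignments(a, "r", regions)
        assert out["mid"].row("r") == "TACG"
        assert out["mid"].row("q") == "TACG"
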