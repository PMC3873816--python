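"""Group-level statistics: mean bias, matched controls, KW association,
Fisher enrichment, Jaccard, cumulative curves, bivalent fractions."""

import itertools
import math

import numpy as np
import pytest

from maesig.allelic_bias import BiasCall
from maesig.cohort_stats import (
    bivalent_overlap_fractions,
    chip_bias_association,
    cumulative_mae_curve,
    enrichment_fisher,
    expression_bin,
    expression_matched_controls,
    gene_bias_score,
    jaccard_similarity,
    mae_fraction_by_expression_bin,
    mean_group_bias,
)


def _call(gene, n_a, n_b, category="biased", direction="a", sample="c1"):
    return BiasCall(gene, sample, n_a, n_b, n_a / (n_a + n_b), 0.0, 0.0, 1.0,
                    category, direction)


class TestGroupBias:
    def test_bias_score_scale(self):
        assert gene_bias_score(50, 50) == 50.0
        assert gene_bias_score(90, 10) == 90.0
        assert gene_bias_score(10, 90) == 90.0  # major allele regardless of side

    def test_group_mean(self):
        calls = [_call("G1", 50, 50), _call("G2", 90, 10)]
        out = mean_group_bias(calls, {"G1": "pred", "G2": "pred"})
        assert out["pred"].mean_bias == pytest.approx(70.0)
        assert out["pred"].n == 2

    def test_empty_group_warns_and_omitted(self):
        with pytest.warns(UserWarning, match="no testable"):
            out = mean_group_bias([_call("G1", 50, 50)], {"G1": "a", "GX": "b"})
        assert set(out) == {"a"}


class TestMatchedControls:
    def test_control_sets_reproduce_target_histogram(self):
        rng = np.random.default_rng(0)
        rpkm = {}
        targets = [f"T{i}" for i in range(40)]
        pool = [f"P{i}" for i in range(400)]
        for g in targets + pool:
            rpkm[g] = float(10 ** rng.uniform(-0.5, 2.0))
        sets = expression_matched_controls(targets, pool, rpkm, n_sets=5, seed=1)
        target_hist = sorted(expression_bin(rpkm[g]) for g in targets)
        for s in sets:
            assert len(s) == len(targets)
            assert sorted(expression_bin(rpkm[g]) for g in s) == target_hist

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(7)
        rpkm = {f"g{i}": float(10 ** rng.uniform(0, 1)) for i in range(300)}
        targets = [f"g{i}" for i in range(30)]
        pool = [f"g{i}" for i in range(30, 300)]
        a = expression_matched_controls(targets, pool, rpkm, n_sets=3, seed=9)
        b = expression_matched_controls(targets, pool, rpkm, n_sets=3, seed=9)
        assert a == b

    def test_pool_smaller_than_targets_rejected(self):
        rpkm = {"a": 1.0, "b": 1.0}
        with pytest.raises(ValueError, match="smaller"):
            expression_matched_controls(["a", "b"], ["c"], {"a": 1, "b": 1, "c": 1})

    def test_shortfall_borrows_from_nearest_bin(self):
        rpkm = {"t1": 1.0, "t2": 1.0, "p1": 1.0, "p2": 100.0}
        with pytest.warns(UserWarning, match="borrowing"):
            (s,) = expression_matched_controls(["t1", "t2"], ["p1", "p2"], rpkm, n_sets=1, seed=0)
        assert sorted(s) == ["p1", "p2"]

    def test_planted_group_difference_detected_by_t_test(self):
        """Targets with planted extra bias separate from expression-matched
        controls across 10 permuted sets (non-paired t-test)."""
        from scipy import stats as ss

        rng = np.random.default_rng(3)
        rpkm, bias = {}, {}
        targets = [f"T{i}" for i in range(40)]
        pool = [f"P{i}" for i in range(400)]
        for g in targets + pool:
            rpkm[g] = float(10 ** rng.uniform(0, 2))
            bias[g] = 60.0 + rng.normal(0, 5)  # background ~60:40
        for g in targets:
            bias[g] += 15.0  # planted effect
        sets = expression_matched_controls(targets, pool, rpkm, n_sets=10, seed=4)
        control_means = [np.mean([bias[g] for g in s]) for s in sets]
        target_mean = np.mean([bias[g] for g in targets])
        t, p = ss.ttest_1samp(control_means, target_mean)
        assert p < 9e-5
        assert target_mean > max(control_means)


class TestMaeFractionByBin:
    def test_all_mae_gives_unit_fractions(self):
        calls = {f"g{i}": "MAE" for i in range(20)}
        rpkm = {f"g{i}": float(i + 1) for i in range(20)}
        out = mae_fraction_by_expression_bin(calls, rpkm)
        assert all(frac == 1.0 for _, _, frac in out.values())

    def test_labels_independent_of_expression_give_half(self):
        rng = np.random.default_rng(1)
        calls, rpkm = {}, {}
        for i in range(4000):
            calls[f"g{i}"] = "MAE" if i % 2 else "BAE"
            rpkm[f"g{i}"] = float(10 ** rng.uniform(0, 1))
        out = mae_fraction_by_expression_bin(calls, rpkm)
        for n_mae, n_other, frac in out.values():
            n = n_mae + n_other
            if n >= 50:
                assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_empty_bins_omitted(self):
        out = mae_fraction_by_expression_bin({"g": "MAE"}, {"g": 1000.0})
        assert list(out) == [expression_bin(1000.0)]


class TestChipAssociation:
    def test_hand_sized_example_matches_textbook_formula(self):
        # 3 groups of 3 distinct values: H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1)
        groups = {"biased_ref": [1.0, 2.0, 3.0], "unbiased": [4.0, 5.0, 6.0],
                  "biased_alt": [7.0, 8.0, 9.0]}
        calls, chip = [], {}
        vals = {"biased_ref": ("biased", "a"), "unbiased": ("unbiased", "none"),
                "biased_alt": ("biased", "b")}
        i = 0
        for label, xs in groups.items():
            cat, d = vals[label]
            for x in xs:
                snp = f"s{i}"; i += 1
                calls.append(_call(snp, 1, 1, cat, d))
                chip[snp] = (int(x * 1000), int((10 - x) * 1000))
        bins, h, p = chip_bias_association(calls, chip)
        ranks = {1: [1, 2, 3], 2: [4, 5, 6], 3: [7, 8, 9]}
        expected_h = 12 / (9 * 10) * sum(sum(r) ** 2 / 3 for r in ranks.values()) - 3 * 10
        assert h == pytest.approx(expected_h)

    def test_null_gives_small_h(self):
        rng = np.random.default_rng(2)
        calls, chip = [], {}
        cats = [("biased", "a"), ("unbiased", "none"), ("biased", "b")]
        for i in range(300):
            cat, d = cats[i % 3]
            calls.append(_call(f"s{i}", 1, 1, cat, d))
            n = 200
            a = int(rng.binomial(n, 0.5))
            chip[f"s{i}"] = (a, n - a)
        _, h, p = chip_bias_association(calls, chip)
        assert p > 0.001

    def test_planted_anticorrelation_detected(self):
        """K27 depleted on the expressed allele: strongly significant at a
        few hundred SNPs."""
        rng = np.random.default_rng(4)
        calls, chip = [], {}
        for i in range(500):
            snp = f"s{i}"
            r = i % 3
            if r == 0:
                calls.append(_call(snp, 95, 5, "biased", "a"))
                p27 = 0.2  # K27 on the silenced (alt) allele
            elif r == 1:
                calls.append(_call(snp, 50, 50, "unbiased", "none"))
                p27 = 0.5
            else:
                calls.append(_call(snp, 5, 95, "biased", "b"))
                p27 = 0.8
            n = 100
            a = int(rng.binomial(n, p27))
            chip[snp] = (a, n - a)
        _, h, p = chip_bias_association(calls, chip)
        assert p < 1e-3

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            chip_bias_association([_call("s0", 9, 1, "biased", "a")], {"s0": (5, 5)})


def brute_fisher_two_sided(n11, n12, n21, n22):
    """Sum of hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table."""
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(n11)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_no_association(self):
        # 2x2 table [[10,10],[10,10]]
        universe = [f"g{i}" for i in range(40)]
        set_a = universe[:20]
        set_b = universe[:10] + universe[20:30]
        odds, p = enrichment_fisher(set_a, set_b, universe)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(9, 1, 1, 9), (3, 7, 6, 4), (0, 10, 10, 0), (12, 3, 2, 13)])
    def test_matches_brute_force_enumeration(self, table):
        n11, n12, n21, n22 = table
        universe = [f"g{i}" for i in range(sum(table))]
        it = iter(universe)
        both = [next(it) for _ in range(n11)]
        only_a = [next(it) for _ in range(n12)]
        only_b = [next(it) for _ in range(n21)]
        _, p = enrichment_fisher(both + only_a, both + only_b, universe)
        assert p == pytest.approx(brute_fisher_two_sided(*table), rel=1e-9)

    def test_perfect_nesting_gives_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        half = universe[:10]
        _, p = enrichment_fisher(half, half, universe)
        # both extreme tables have equal probability, so the two-tailed
        # minimum for these margins is twice the hypergeometric point mass
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(brute_fisher_two_sided(10, 0, 0, 10), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fisher([], [], [])


class TestJaccard:
    def test_half_overlap(self):
        mat = jaccard_similarity({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
        assert mat[0, 1] == pytest.approx(0.5)

    def test_identity_diagonal_and_symmetry(self):
        mat = jaccard_similarity({"x": {"A"}, "y": {"A", "B"}, "z": {"C"}})
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat, mat.T)
        assert mat[0, 2] == 0.0

    def test_both_empty_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            mat = jaccard_similarity({"x": set(), "y": set()})
        assert mat[0, 1] == 0.0


class TestCumulativeCurve:
    def test_identical_sets_flat_curve(self):
        s = {"a", "b", "c"}
        curve = cumulative_mae_curve({"l1": s, "l2": s, "l3": s})
        assert [m for m, _ in curve] == [3.0, 3.0, 3.0]
        assert all(sd == 0.0 for _, sd in curve)

    def test_disjoint_sets_linear_curve(self):
        sets = {"l1": {"a"}, "l2": {"b"}, "l3": {"c"}}
        curve = cumulative_mae_curve(sets)
        assert [m for m, _ in curve] == [1.0, 2.0, 3.0]
        assert all(sd == 0.0 for _, sd in curve)

    def test_matches_exhaustive_ordering_enumeration(self):
        sets = {"l1": {"a", "b"}, "l2": {"b", "c", "d"}, "l3": {"a", "e"}}
        curve = cumulative_mae_curve(sets)
        sizes = []
        for order in itertools.permutations(sets):
            seen, row = set(), []
            for name in order:
                seen |= sets[name]
                row.append(len(seen))
            sizes.append(row)
        expected = np.array(sizes, dtype=float)
        for k in range(3):
            assert curve[k][0] == pytest.approx(expected[:, k].mean())
            assert curve[k][1] == pytest.approx(expected[:, k].std())

    def test_curve_non_decreasing_and_final_value_order_invariant(self):
        rng = np.random.default_rng(5)
        sets = {f"l{i}": set(rng.choice(50, size=15, replace=False).tolist()) for i in range(5)}
        curve = cumulative_mae_curve(sets)
        means = [m for m, _ in curve]
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert curve[-1][1] == pytest.approx(0.0)
        assert curve[-1][0] == len(set().union(*sets.values()))

    def test_common_universe_restricts_to_shared_expression(self):
        mae = {"l1": {"a", "x"}, "l2": {"a", "y"}}
        expressed = {"l1": {"a", "x", "c"}, "l2": {"a", "y", "c"}}
        curve = cumulative_mae_curve(mae, expressed, universe_mode="common")
        assert curve[-1][0] == 1.0  # only "a" expressed in both


class TestBivalentFractions:
    def test_full_overlap_gives_one(self):
        groups = {"g1": "bivalent", "g2": "bivalent"}
        out = bivalent_overlap_fractions({"g1", "g2"}, groups)
        assert out["bivalent"] == 1.0

    def test_planted_fractions_recovered(self):
        rng = np.random.default_rng(6)
        groups, mae_any = {}, set()
        planted = {"bivalent": 0.85, "not_bivalent_silent_hESC": 0.3,
                   "not_bivalent_expressed_hESC": 0.3}
        for label, frac in planted.items():
            for i in range(500):
                g = f"{label}_{i}"
                groups[g] = label
                if rng.random() < frac:
                    mae_any.add(g)
        out = bivalent_overlap_fractions(mae_any, groups)
        for label, frac in planted.items():
            se = math.sqrt(frac * (1 - frac) / 500)
            assert abs(out[label] - frac) < 3 * se
        assert out["bivalent"] > 0.8

    def test_empty_group_reports_nan(self):
        out = bivalent_overlap_fractions(set(), {})
        assert out == {}
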