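"""Trial statistics: enumeration oracles, printed-table reproductions,
independent cross-checks (values validated against R's wilcox.test and the
normal-approximation sample-size bound)."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from hypotrial.stats import (PowerSpec, bonferroni, chi_square_2x2,
                             compare_proportions, expected_counts, fisher_2x2,
                             hodges_lehmann, inflate_for_dropout, mann_whitney,
                             power_two_means, proportion_diff_ci,
                             sample_size_two_means, select_test,
                             t_test_from_summary)


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value == 1.0

    def test_fully_separated_triples(self):
        # U=0; exact enumeration of C(6,3)=20 assignments: 2/20
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(0.1)

    def test_exact_equals_full_enumeration_with_ties(self, rng):
        # independent enumeration over index subsets, tie-aware U
        for _ in range(5):
            x = rng.integers(0, 5, size=6).astype(float)
            y = rng.integers(0, 5, size=7).astype(float)
            pooled = np.concatenate([x, y])
            n = x.size

            def u_of(ix):
                xa = pooled[list(ix)]
                ya = np.delete(pooled, list(ix))
                return (xa[:, None] > ya[None, :]).sum() + 0.5 * (
                    xa[:, None] == ya[None, :]).sum()

            u_obs = u_of(range(n))
            dev = abs(u_obs - n * y.size / 2)
            hits = sum(abs(u_of(c) - n * y.size / 2) >= dev - 1e-12
                       for c in combinations(range(pooled.size), n))
            total = math.comb(pooled.size, n)
            assert mann_whitney(x, y).p_value == pytest.approx(hits / total)

    def test_asymptotic_close_to_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.5, 1.0, 30)
        p_asym = mann_whitney(x, y).p_value
        # Monte-Carlo permutation of the rank-sum statistic
        ranks = sps.rankdata(np.concatenate([x, y]))
        obs = abs(ranks[:30].sum() - 30 * 61 / 2)
        nperm = 100_000
        perm = np.argsort(rng.random((nperm, 60)), axis=1)[:, :30]
        stat = np.abs(ranks[perm].sum(axis=1) - 30 * 61 / 2)
        p_mc = float((stat >= obs - 1e-9).mean())
        assert p_asym == pytest.approx(p_mc, abs=0.005)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestHodgesLehmann:
    def test_shift_recovery(self):
        x = [1.0, 4.0, 2.5, 7.0]
        y = [v + 3.0 for v in x]
        assert hodges_lehmann(x, y).estimate == pytest.approx(3.0)

    def test_small_example_all_pairs(self):
        # pairwise differences y-x: {1, 3, 0, 2} -> median 1.5
        r = hodges_lehmann([1.0, 2.0], [2.0, 4.0])
        assert r.estimate == pytest.approx(1.5)

    def test_equals_brute_force_oracle(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 2, 30)
        diffs = sorted(yy - xx for xx in x for yy in y)  # O(n^2) oracle
        n = len(diffs)
        med = (diffs[n // 2 - 1] + diffs[n // 2]) / 2 if n % 2 == 0 else diffs[n // 2]
        assert hodges_lehmann(x, y).estimate == pytest.approx(med)

    def test_against_r_wilcox_reference(self):
        # frozen reference computed with R wilcox.test(y, x, conf.int=TRUE,
        # exact=FALSE, correct=FALSE) on these exact draws
        rng = np.random.default_rng(7)
        x = np.round(rng.normal(10, 2, 30), 2)
        y = np.round(rng.normal(12, 2, 30), 2)
        r = hodges_lehmann(x, y)
        assert r.estimate == pytest.approx(2.73, abs=1e-6)
        assert r.ci_low == pytest.approx(1.76, abs=0.02)
        assert r.ci_high == pytest.approx(3.65, abs=0.02)
        assert r.p_value == pytest.approx(4.986168e-07, rel=1e-4)

    def test_ci_contains_estimate(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0.3, 1, 18)
            r = hodges_lehmann(x, y)
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_ci_coverage_near_nominal(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0, 1, 20)
            y = rng.normal(1.0, 1, 20)
            r = hodges_lehmann(x, y)
            hits += r.ci_low <= 1.0 <= r.ci_high
        assert 0.90 <= hits / reps <= 0.99


class TestTTestFromSummary:
    def test_identical_summaries(self):
        r = t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert r.estimate == 0.0 and r.p_value == pytest.approx(1.0)

    def test_age_row(self):
        # group means 60.17+-10.6 vs 59.70+-10.3, n=30 each
        r = t_test_from_summary(60.17, 10.6, 30, 59.70, 10.3, 30)
        assert round(r.p_value, 2) == 0.86

    def test_fluid_balance_ci_uses_t_critical(self):
        r = t_test_from_summary(1404.6, 1512.5, 30, 1810.7, 983.9, 30)
        assert r.estimate == pytest.approx(406.1)
        # z-based half-width would give ~1051.8 here; t-critical reproduces
        # the reported interval
        assert r.ci_high == pytest.approx(1065.5, abs=0.1)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 30)


class TestContingency:
    def test_chi_square_without_continuity_correction(self):
        # 6/30 vs 14/30: Pearson chi2 = 4.8
        r = chi_square_2x2(6, 24, 14, 16)
        assert round(r.p_value, 3) == 0.028

    def test_fisher_two_sided(self):
        r = fisher_2x2(3, 27, 6, 24)
        assert round(r.p_value, 2) == 0.47

    def test_balanced_table_is_null(self):
        r = chi_square_2x2(5, 5, 5, 5)
        assert r.p_value == pytest.approx(1.0)

    def test_chi_square_row_column_symmetry(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(1, 30, size=4)
            p1 = chi_square_2x2(a, b, c, d).p_value
            p2 = chi_square_2x2(a, c, b, d).p_value  # transpose
            assert p1 == pytest.approx(p2)

    def test_fisher_p_at_least_point_probability(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(0, 15, size=4) + [1, 1, 1, 1]
            p = fisher_2x2(a, b, c, d).p_value
            point = sps.hypergeom.pmf(a, a + b + c + d, a + b, a + c)
            assert p >= point - 1e-12

    def test_selection_rule(self):
        # 3/27 vs 6/24: expected events per cell 4.5 -> half the cells < 5
        assert select_test(3, 27, 6, 24) == "fisher"
        assert select_test(15, 15, 15, 15) == "chi_square"
        assert compare_proportions(3, 27, 6, 24).test_name == "fisher_exact"

    def test_expected_counts(self):
        exp = expected_counts(3, 27, 6, 24)
        assert exp[0, 0] == pytest.approx(4.5)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


class TestProportionDiffCI:
    def test_equal_proportions_symmetric(self):
        r = proportion_diff_ci(5, 30, 5, 30)
        assert r.estimate == 0.0
        assert r.ci_low == pytest.approx(-r.ci_high)

    def test_nicardipine_row(self):
        r = proportion_diff_ci(9, 30, 6, 30)
        assert r.estimate == pytest.approx(10.0)
        assert round(r.ci_high, 1) == 35.1

    def test_ephedrine_row(self):
        r = proportion_diff_ci(5, 30, 6, 30)
        assert round(r.ci_low, 1) == -26.2
        assert round(r.ci_high, 1) == 19.6

    def test_contains_point_estimate(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(5, 50)), int(rng.integers(5, 50))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            r = proportion_diff_ci(x1, n1, x2, n2)
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_diff_ci(0, 0, 1, 10)


class TestSampleSize:
    def test_design_assumptions_give_54_then_60(self):
        out = sample_size_two_means(PowerSpec())
        assert out["n_total"] == 54
        assert inflate_for_dropout(out["n_total"], 0.10) == 60

    def test_power_brackets_the_target(self):
        out = sample_size_two_means(PowerSpec())
        n = out["n_per_group"]
        assert power_two_means(n, 0.25, 0.32, 0.05) >= 0.80
        assert power_two_means(n - 1, 0.25, 0.32, 0.05) < 0.80

    def test_at_least_normal_approximation_bound(self):
        # closed form: n ~ 2 (z_{1-a/2}+z_{1-b})^2 sigma^2 / delta^2 = 25.7;
        # the noncentral-t refinement must return at least this
        z = sps.norm.ppf
        n_norm = 2 * (z(0.975) + z(0.8)) ** 2 * 0.32 ** 2 / 0.25 ** 2
        assert n_norm == pytest.approx(25.72, abs=0.05)
        assert sample_size_two_means(PowerSpec())["n_per_group"] >= n_norm

    def test_monotone_in_sd_and_delta(self):
        base = sample_size_two_means(PowerSpec())["n_total"]
        wider = sample_size_two_means(PowerSpec(sd=0.64))["n_total"]
        closer = sample_size_two_means(PowerSpec(mu_control=0.30))["n_total"]
        assert wider > base
        assert closer > base

    def test_agrees_with_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower
        n_sm = TTestIndPower().solve_power(effect_size=0.25 / 0.32, alpha=0.05,
                                           power=0.80, alternative="two-sided")
        assert sample_size_two_means(PowerSpec())["n_per_group"] == math.ceil(n_sm)

    def test_dropout_arithmetic(self):
        assert inflate_for_dropout(54, 0.0) == 54
        assert inflate_for_dropout(17, 0.5) == 34
        with pytest.raises(ValueError):
            inflate_for_dropout(54, 1.0)


class TestBonferroni:
    def test_family_scaling_and_decisions(self):
        out = bonferroni([0.028, 0.001], family_size=10)
        assert out[0]["p_adjusted"] == pytest.approx(0.28)
        assert not out[0]["significant"]
        assert out[1]["p_adjusted"] == pytest.approx(0.01)
        assert out[1]["significant"]

    def test_family_of_one_is_identity(self):
        out = bonferroni([0.04], family_size=1)
        assert out[0]["p_adjusted"] == 0.04
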