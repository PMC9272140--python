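import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairgaze.stats_battery import (
    anova_factorial,
    chi2_contingency,
    chi2_proportion,
    pearson_r,
    tukey_hsd,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

from oracles import rank_sum_exact_p, signed_rank_dp_p, signed_rank_exact_p


class TestSignedRank:
    def test_three_negative_diffs(self):
        res = wilcoxon_signed_rank([-1, -1, -1])
        assert res.statistic == 0
        assert res.p == pytest.approx(0.25)  # 2 * (1/8)

    def test_perfectly_symmetric_pair(self):
        assert wilcoxon_signed_rank([-1, 1]).p == pytest.approx(1.0)

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([0, 0, -1, -1, -1])
        assert res.n == 3
        assert res.p == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_branch_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        d = np.round(rng.normal(0, 1, n), 1)
        d = d[d != 0]
        if len(d) == 0:
            return
        res = wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(signed_rank_exact_p(d), abs=1e-12)

    def test_large_n_approximation_near_exact(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.2, 1, 30)  # ties-free with probability 1
        res = wilcoxon_signed_rank(d)
        assert "approximation" in res.method
        assert res.p == pytest.approx(signed_rank_dp_p(d), abs=0.005)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1, 15)
        assert wilcoxon_signed_rank(d).p == pytest.approx(wilcoxon_signed_rank(-d).p)


class TestRankSum:
    def test_fully_separated_small_samples(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p == pytest.approx(2 / 6)

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0, 1, int(rng.integers(2, 7))), 1)
        b = np.round(rng.normal(0.5, 1, int(rng.integers(2, 7))), 1)
        res = wilcoxon_rank_sum(a, b)
        assert "exact" in res.method
        assert res.p == pytest.approx(rank_sum_exact_p(a, b), abs=1e-12)

    def test_power_at_one_sd_shift(self):
        """delta = 1 SD, n = 50/50: rejection rate comfortably above 0.8."""
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            if wilcoxon_rank_sum(a, b).p < 0.05:
                hits += 1
        assert hits / reps > 0.8

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.3, 1, 25)
        assert wilcoxon_rank_sum(a, b).p == pytest.approx(wilcoxon_rank_sum(b, a).p)


class TestChi2:
    def test_seventy_eight_of_hundred(self):
        res = chi2_proportion(78, 100, 0.5)
        assert res.statistic == pytest.approx(31.36)
        assert res.df == 1

    def test_null_proportion_exact(self):
        res = chi2_proportion(50, 100, 0.5)
        assert res.statistic == 0
        assert res.p == pytest.approx(1.0)

    def test_identical_rows_independent(self):
        res = chi2_contingency(np.array([[20, 30], [20, 30]]))
        assert res.statistic == pytest.approx(0.0)

    def test_tiny_expected_count_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            chi2_proportion(0, 10, 0.01)


class TestAnova:
    def test_one_way_hand_computed(self):
        res = anova_factorial([1, 2, 3, 3, 4, 5], {"g": ["a"] * 3 + ["b"] * 3})
        assert res[0].statistic == pytest.approx(6.0)
        assert res[0].df == (1, 4)

    def test_additive_cells_zero_interaction(self):
        # balanced 2x2, exactly additive means, no noise
        a = ["lo", "lo", "hi", "hi"] * 2
        b = ["x", "y"] * 4
        y = [
            {"lo": 0, "hi": 2}[ai] + {"x": 0, "y": 5}[bi]
            for ai, bi in zip(a, b)
        ]
        res = anova_factorial(y, {"a": a, "b": b}, include_interactions=True)
        inter = [r for r in res if r.test == "anova[a:b]"][0]
        assert inter.statistic == pytest.approx(0.0, abs=1e-18)

    def test_one_way_f_equals_squared_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 15)
        res = anova_factorial(
            np.concatenate([x, y]), {"g": ["x"] * 12 + ["y"] * 15}
        )[0]
        t, p = stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_matches_statsmodels_type2_on_unbalanced_three_way(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        n = 120
        df = pd.DataFrame(
            {
                "a": rng.choice(["a1", "a2"], n),
                "b": rng.choice(["b1", "b2", "b3"], n),
                "c": rng.choice(["c1", "c2"], n),
            }
        )
        df["y"] = (
            rng.normal(0, 1, n)
            + (df["a"] == "a2") * 0.5
            + (df["b"] == "b3") * 0.8
            + ((df["a"] == "a2") & (df["c"] == "c2")) * 0.6
        )
        ours = anova_factorial(df["y"], df[["a", "b", "c"]], include_interactions=True)
        fit = smf.ols("y ~ C(a) * C(b) * C(c)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for r in ours:
            term = r.test[len("anova[") : -1]
            key = ":".join(f"C({f})" for f in term.split(":"))
            assert r.statistic == pytest.approx(ref.loc[key, "F"], rel=1e-6), term
            assert r.p == pytest.approx(ref.loc[key, "PR(>F)"], rel=1e-6), term

    def test_empty_cell_named_in_error(self):
        a = ["a1", "a1", "a2", "a2"]
        b = ["b1", "b1", "b1", "b1"]
        with pytest.raises(ValueError):
            anova_factorial([1, 2, 3, 4], {"a": a, "b": b}, include_interactions=True)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            anova_factorial([1, 2, 3], {"g": ["a", "a", "a"]})


class TestTukey:
    def test_identical_groups_no_rejection(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 10)
        y = np.concatenate([base, base, base])
        g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        out = tukey_hsd(y, g)
        assert (out["p_adj"] > 0.99).all()

    def test_two_groups_equal_t_test(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10)
        y = rng.normal(1, 1, 10)
        out = tukey_hsd(np.concatenate([x, y]), ["x"] * 10 + ["y"] * 10)
        _, p_t = stats.ttest_ind(x, y)
        assert out["p_adj"].iloc[0] == pytest.approx(p_t, rel=1e-5)

    def test_matches_statsmodels_and_range_cdf(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        y = np.concatenate(
            [rng.normal(0, 1, 12), rng.normal(0.7, 1, 12), rng.normal(1.5, 1, 12)]
        )
        g = np.repeat(["a", "b", "c"], 12)
        ours = tukey_hsd(y, g)
        ref = pairwise_tukeyhsd(y, g)
        for row, p_ref in zip(ours.itertuples(), ref.pvalues):
            assert row.p_adj == pytest.approx(p_ref, abs=1e-4)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            tukey_hsd([1, 2, 3], ["a", "a", "a"])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        res = pearson_r(x, y)
        reps = 100_000
        perm_r = np.empty(reps)
        for k in range(reps):
            perm_r[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (np.abs(perm_r) >= abs(res.statistic) - 1e-12).mean()
        # Monte-Carlo error ~ 3*sqrt(p(1-p)/reps)
        assert res.p == pytest.approx(p_perm, abs=3 * math.sqrt(p_perm * (1 - p_perm) / reps) + 0.01)


class TestTwoTailedContract:
    def test_all_battery_p_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1, 18)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 14)
        results = [
            wilcoxon_signed_rank(d),
            wilcoxon_rank_sum(a, b),
            chi2_proportion(60, 100),
            pearson_r(a, a * 0.5 + rng.normal(0, 1, 12)),
            *anova_factorial(np.concatenate([a, b]), {"g": ["a"] * 12 + ["b"] * 14}),
        ]
        for res in results:
            assert 0.0 <= res.p <= 1.0
            # two-tailed: flipping every sign / swapping groups keeps p
        assert wilcoxon_signed_rank(-d).p == pytest.approx(wilcoxon_signed_rank(d).p)
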