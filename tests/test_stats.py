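import itertools

import numpy as np
import pytest
from scipy import stats as sps

from patkit.published import CLASSIFICATION_TABLES, table_counts
from patkit.stats import (
    chisq_test,
    oneway_anova,
    pooled_t_test,
    power_two_sample,
    rank_sum_test,
    residualize,
    spearman,
)


class TestPooledT:
    def test_identical_groups(self):
        r = pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_direction_follows_mean_difference(self):
        r = pooled_t_test([101.0, 102.0, 103.0], [1.0, 2.0, 3.0])
        assert r.statistic > 10
        assert r.p_value < 1e-6

    def test_df_is_n_minus_2(self, rng):
        a, b = rng.normal(size=163), rng.normal(size=103)
        assert pooled_t_test(a, b).df == 264.0

    def test_matches_scipy_closed_form(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(loc=0.3, size=rng.integers(5, 40))
            r = pooled_t_test(a, b)
            t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
            assert r.statistic == pytest.approx(t_ref, abs=1e-12)
            assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_label_swap_flips_sign(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.5, size=25)
        assert pooled_t_test(a, b).statistic == pytest.approx(
            -pooled_t_test(b, a).statistic
        )


published_cases = [
    (sample, level, entry["reported_chisq"])
    for sample, levels in CLASSIFICATION_TABLES.items()
    for level, entry in levels.items()
]


class TestChisq:
    @pytest.mark.parametrize("sample,level,reported", published_cases)
    def test_reproduces_published_tables(self, sample, level, reported):
        """Every published classification chi-squared to 3 decimals."""
        r = chisq_test(table_counts(sample, level))
        assert r.statistic == pytest.approx(reported, abs=5e-4)
        assert r.df == (1.0 if level == "bf30" else 2.0)

    def test_independent_proportions_give_zero(self):
        assert chisq_test([[10, 20, 30], [20, 40, 60]]).statistic == pytest.approx(0.0)

    def test_2x2_closed_form(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(1, 60, size=4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert chisq_test([[a, b], [c, d]]).statistic == pytest.approx(expected)

    def test_all_zero_column_dropped(self):
        with_zero = chisq_test([[0, 5, 10], [0, 10, 5]])
        without = chisq_test([[5, 10], [10, 5]])
        assert with_zero.statistic == pytest.approx(without.statistic)
        assert with_zero.df == 1.0

    def test_reduced_below_2x2_rejected(self):
        with pytest.raises(ValueError):
            chisq_test([[0, 5], [0, 10]])


class TestRankSum:
    def test_identical_samples_z_zero(self):
        r = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=15)
        r1 = rank_sum_test(a, b)
        r2 = rank_sum_test(a + 100.0, b + 100.0)
        assert r1.extra["u"] == r2.extra["u"]
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_scipy_without_continuity(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.4, size=25)
        r = rank_sum_test(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert r.extra["u"] == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_ordering_agrees_with_exact_permutation(self, rng):
        # small untied samples: normal-approximation p orders cases the
        # same way as the exact permutation distribution of U
        cases = [
            ([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]),
            ([1.0, 5.0, 3.0, 7.0], [2.0, 6.0, 4.0, 8.0]),
        ]
        approx_p, exact_p = [], []
        for a, b in cases:
            approx_p.append(rank_sum_test(a, b).p_value)
            pooled = a + b
            u_obs = rank_sum_test(a, b).extra["u"]
            mu = len(a) * len(b) / 2.0
            count = total = 0
            for idx in itertools.combinations(range(8), 4):
                grp = [pooled[i] for i in idx]
                rest = [pooled[i] for i in range(8) if i not in idx]
                u = sum(1 for x in grp for y in rest if x > y) + 0.5 * sum(
                    1 for x in grp for y in rest if x == y
                )
                total += 1
                count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
            exact_p.append(count / total)
        assert (approx_p[0] < approx_p[1]) == (exact_p[0] < exact_p[1])

    def test_tie_correction_applied(self):
        # heavy ties shrink the variance; the corrected Z must exceed the
        # uncorrected one computed by hand
        a = [1.0, 1.0, 2.0, 2.0, 3.0]
        b = [2.0, 3.0, 3.0, 4.0, 4.0]
        r = rank_sum_test(a, b)
        n1 = n2 = 5
        var_uncorrected = n1 * n2 * (n1 + n2 + 1) / 12.0
        z_uncorrected = abs(r.extra["u"] - n1 * n2 / 2.0) / np.sqrt(var_uncorrected)
        assert r.statistic > z_uncorrected

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0, 1.0], [1.0, 1.0])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 4.0, 5.0, 20.0]).statistic == pytest.approx(1.0)
        assert spearman(x, [20.0, 5.0, 4.0, 2.0]).statistic == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0]
        rho = spearman(x, y).statistic
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestResidualize:
    def test_orthogonal_covariate_centers_y(self, rng):
        y = rng.normal(size=50)
        yc = y - y.mean()
        x = rng.normal(size=50)
        x -= x.mean()
        x -= (x @ yc) / (yc @ yc) * yc  # now orthogonal to intercept and y
        resid = residualize(y, x)
        assert resid == pytest.approx(yc, abs=1e-10)

    def test_normal_equations(self, rng):
        y = rng.normal(size=80)
        X = rng.normal(size=(80, 3))
        resid = residualize(y, X)
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)
        for j in range(3):
            assert np.corrcoef(resid, X[:, j])[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        y = rng.normal(size=20)
        x = np.ones(20)
        with pytest.raises(ValueError, match="rank"):
            residualize(y, x)

    def test_known_signal_removed(self, rng):
        hr = rng.normal(75.0, 8.0, size=200)
        y = 2.0 * hr + rng.normal(size=200)
        resid = residualize(y, hr)
        assert np.corrcoef(resid, hr)[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert resid.std() < 2.0


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        r = oneway_anova([g, g, g, g])
        assert r.statistic == pytest.approx(0.0)
        assert r.df == 3.0

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(size=15), rng.normal(0.4, size=12)
        f = oneway_anova([a, b])
        t = pooled_t_test(a, b)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p_value == pytest.approx(t.p_value)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(loc=i * 0.2, size=rng.integers(8, 20)) for i in range(4)]
        r = oneway_anova(groups)
        ref = sps.f_oneway(*groups)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)
        assert r.df == 3.0
        assert r.extra["df_within"] == sum(len(g) for g in groups) - 4


class TestPower:
    def test_study_design_exceeds_95_percent(self):
        assert power_two_sample(0.5, 163, 103) > 0.95

    def test_null_limit_is_alpha(self):
        assert power_two_sample(1e-8, 50, 50) == pytest.approx(0.05, abs=1e-4)

    def test_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        ref = smp.TTestIndPower().power(
            effect_size=0.5, nobs1=163, ratio=103 / 163, alpha=0.05
        )
        assert power_two_sample(0.5, 163, 103) == pytest.approx(ref, abs=1e-6)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample(0.5, 50, 50, alpha=1.5)
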