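import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mmith.cohort_stats import (
    chi_square_2x2,
    cox_ph,
    kendall_tau_b,
    km_logrank,
    median_split,
    one_way_anova,
    spearman_rho,
    wilcoxon_rank_sum,
)
from mmith.errors import DomainError


class TestMedianSplit:
    def test_even(self):
        low, high = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert set(low) == {"a", "b"} and set(high) == {"c", "d"}

    def test_odd_median_goes_low(self):
        low, high = median_split({"a": 1, "b": 2, "c": 3})
        assert set(low) == {"a", "b"} and set(high) == {"c"}

    def test_43_values_split_22_21(self, rng):
        vals = {f"p{i}": float(v) for i, v in enumerate(rng.normal(size=43))}
        low, high = median_split(vals)
        assert (len(low), len(high)) == (22, 21)


class TestKendall:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert kendall_tau_b(x, x).statistic == pytest.approx(1.0)
        assert kendall_tau_b(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_hand_value(self):
        # 5 concordant, 1 discordant pairs -> (5-1)/6
        r = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.statistic == pytest.approx(4 / 6, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(0, 3, 20)
        assert spearman_rho(x, np.exp(x)).statistic == pytest.approx(1.0)

    def test_midrank_ties_hand_value(self):
        r = spearman_rho([1, 1, 2], [1, 2, 3])
        assert r.statistic == pytest.approx(np.sqrt(3) / 2, abs=1e-9)  # 0.866

    def test_null_is_small_at_large_n(self, rng):
        x = rng.normal(size=1000)
        y = rng.permutation(rng.normal(size=1000))
        assert abs(spearman_rho(x, y).statistic) < 0.1


class TestWilcoxon:
    def test_identical_samples_p_near_one(self, rng):
        a = rng.normal(size=30)
        assert wilcoxon_rank_sum(a, a).p_value > 0.9

    def test_exact_small_sample(self):
        # U = 0; two-sided exact p = 2 * 1/C(6,3) = 0.1
        r = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert "exact" in r.method

    def test_power_under_shift(self, rng):
        rejections = 0
        for _ in range(200):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            if wilcoxon_rank_sum(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.9


class TestChiSquare:
    def test_remission_table(self):
        """Uncorrected Pearson chi-square on the 8/22 vs 14/21 response table."""
        r = chi_square_2x2([[8, 14], [14, 7]])
        # closed form: 43*(8*7 - 14*14)^2 / (22*21*22*21)
        assert r.statistic == pytest.approx(43 * (8 * 7 - 14 * 14) ** 2 / (22 * 21) ** 2)
        assert round(r.p_value, 3) == 0.047
        assert r.extra["proportions"][0] == pytest.approx(8 / 22)   # 36.4%
        assert r.extra["proportions"][1] == pytest.approx(14 / 21)  # 66.7%

    def test_balanced_table_null(self):
        r = chi_square_2x2([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestKMLogrank:
    def test_identical_groups_null(self):
        recs = [(float(t), True) for t in (3, 6, 9, 12)]
        r, curves = km_logrank({"a": recs, "b": list(recs)})
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        """Six uncensored subjects, fully separated groups: hand table gives
        O=3, E=1.15, V=0.6775 -> chi2 = 1.85^2/0.6775."""
        r, _ = km_logrank(
            {"A": [(1, True), (2, True), (3, True)],
             "B": [(10, True), (20, True), (30, True)]}
        )
        assert r.statistic == pytest.approx((3 - 1.15) ** 2 / 0.6775, abs=1e-6)

    def test_all_censored_flat_curves(self):
        r, curves = km_logrank(
            {"a": [(5, False), (8, False)], "b": [(3, False), (9, False)]}
        )
        for df in curves.values():
            assert np.allclose(df["survival"], 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            km_logrank({"a": [(1, True)], "b": []})

    def test_within_group_order_invariance(self, rng):
        recs = [(float(t), bool(e)) for t, e in
                zip(rng.exponential(10, 20), rng.random(20) < 0.7)]
        other = [(float(t), True) for t in rng.exponential(5, 15)]
        r1, _ = km_logrank({"a": recs, "b": other})
        r2, _ = km_logrank({"a": list(reversed(recs)), "b": other})
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


class TestCoxPH:
    def test_null_binary_covariate(self, rng):
        t = np.concatenate([rng.exponential(10, 50)] * 2)
        x = np.repeat([0.0, 1.0], 50)
        fit = cox_ph(pd.DataFrame({"x": x}), t, np.ones(100, dtype=bool))
        (eff,) = fit.covariates
        assert 0.7 < eff.hazard_ratio < 1.4
        assert fit.converged

    def test_parameter_recovery_hr2(self):
        """Exponential PH with true HR 2: median estimate within [1.8, 2.2]."""
        hrs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.integers(0, 2, 500).astype(float)
            t = r.exponential(1.0 / np.exp(np.log(2.0) * x))
            c = r.random(500) < 0.15
            obs = np.where(c, t * r.random(500), t)
            fit = cox_ph(pd.DataFrame({"x": x}), obs, ~c)
            hrs.append(fit.covariates[0].hazard_ratio)
        assert 1.8 <= float(np.median(hrs)) <= 2.2

    def test_eight_covariate_panel_shape(self, rng):
        """The study's covariate panel yields one HR row per covariate."""
        n = 120
        cov = pd.DataFrame(
            {
                "math": rng.normal(55, 20, n),
                "fish": rng.integers(0, 2, n).astype(float),
                "iss": rng.integers(1, 4, n).astype(float),
                "male": rng.integers(0, 2, n).astype(float),
                "age": rng.normal(60, 8, n),
                "ecog": rng.integers(0, 3, n).astype(float),
                "hyperdiploid": rng.integers(0, 2, n).astype(float),
                "lightchain": rng.integers(0, 2, n).astype(float),
            }
        )
        t = rng.exponential(20, n)
        fit = cox_ph(cov, t, rng.random(n) < 0.6)
        assert len(fit.covariates) == 8
        for eff in fit.covariates:
            assert eff.ci95_low <= eff.hazard_ratio <= eff.ci95_high

    def test_constant_covariate_rejected(self):
        with pytest.raises(DomainError):
            cox_ph(pd.DataFrame({"x": [1.0] * 10}), np.arange(1, 11),
                   np.ones(10, dtype=bool))


class TestANOVA:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        r = one_way_anova([g, list(g), list(g)])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_two_groups_is_squared_t(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        f = one_way_anova([a, b]).statistic
        t = sps.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_power_with_shifted_group(self, rng):
        hits = 0
        for _ in range(200):
            groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
            if one_way_anova(groups).p_value < 0.01:
                hits += 1
        assert hits / 200 >= 0.95


class TestNullUniformity:
    def test_pvalues_uniform_under_null(self, rng):
        """KS distance of null p-values from U(0,1) stays small."""
        pvals_k, pvals_w = [], []
        for _ in range(300):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            pvals_k.append(kendall_tau_b(x, y).p_value)
            pvals_w.append(wilcoxon_rank_sum(x, y).p_value)
        for pvals in (pvals_k, pvals_w):
            d = sps.kstest(pvals, "uniform").statistic
            assert d < 0.1
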