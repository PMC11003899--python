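"""Statistical-procedure contracts: the normality gate's operating
characteristics, gated group comparison, categorical tests, correlation
estimators, median split, and the regression screening strategy."""

import numpy as np
import pandas as pd
import pytest

from glomkit.stats import (
    chi_squared_test,
    compare_by_median_split,
    compare_groups,
    correlate,
    median_split,
    normality_gate,
    regression_strategy,
)


class TestNormalityGate:
    def test_accepts_gaussian_samples(self):
        rng = np.random.default_rng(1)
        hits = sum(
            normality_gate(rng.normal(0, 1, 500)).is_normal for _ in range(1000)
        )
        assert hits >= 930

    def test_rejects_lognormal_samples(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            not normality_gate(np.exp(rng.normal(0, 1, 500))).is_normal
            for _ in range(1000)
        )
        assert rejections >= 990

    def test_constant_vector_is_degenerate(self):
        d = normality_gate(np.full(20, 3.0))
        assert d.degenerate and not d.is_normal

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestCompareGroups:
    def test_identical_samples_take_t_branch_with_p_one(self, rng):
        x = rng.normal(0, 1, 54)
        res = compare_groups(x, x)
        assert res.test_used == "t"
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_skewed_data_takes_rank_branch(self, rng):
        x = np.exp(rng.normal(0, 1, 54))
        y = np.exp(rng.normal(0, 1, 32))
        assert compare_groups(x, y).test_used == "wilcoxon"

    def test_branch_is_pure_function_of_samples(self, rng):
        x = rng.normal(0, 1, 54)
        y = rng.normal(0, 1, 32)
        assert compare_groups(x, y).test_used == compare_groups(x, y).test_used

    def test_power_at_one_sd_shift(self):
        """d = 1 SD at n = 54 vs 32 should be detected almost always."""
        rng = np.random.default_rng(3)
        hits = sum(
            compare_groups(rng.normal(0, 1, 54), rng.normal(1, 1, 32)).p_value < 0.05
            for _ in range(1000)
        )
        assert hits / 1000 > 0.9

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.ones(10), np.ones(10))


class TestChiSquared:
    def test_smoker_table_is_null(self):
        # 12/54 vs 7/32 current smokers: virtually identical proportions
        res = chi_squared_test([[12, 42], [7, 25]])
        assert res.p_value > 0.9

    def test_balanced_table_statistic_zero(self):
        assert chi_squared_test([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(1, 60, (2, 2)).astype(float)
            res = chi_squared_test(t)
            row = t.sum(axis=1, keepdims=True)
            col = t.sum(axis=0, keepdims=True)
            expected = row * col / t.sum()
            assert res.statistic == pytest.approx(((t - expected) ** 2 / expected).sum())

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_test([[0, 0], [5, 3]])


class TestCorrelate:
    def test_perfect_correlation(self, rng):
        x = rng.normal(0, 1, 30)
        assert correlate(x, x).r == pytest.approx(1.0)

    def test_permutation_null_is_centered(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        rs = [correlate(x, rng.permutation(y)).r for _ in range(500)]
        assert abs(np.mean(rs)) < 0.05

    def test_planted_negative_correlation_recovered(self):
        """ρ = −0.48 at n = 32 (the women-subgroup scale): estimator unbiased."""
        rng = np.random.default_rng(5)
        rho = -0.48
        cov = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((2000, 32, 2)) @ L.T
        xc = z[..., 0] - z[..., 0].mean(axis=1, keepdims=True)
        yc = z[..., 1] - z[..., 1].mean(axis=1, keepdims=True)
        rs = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        assert abs(rs.mean() - rho) < 0.05
        # the package estimator agrees with the direct formula on one draw
        res = correlate(z[0, :, 0], z[0, :, 1])
        assert res.r == pytest.approx(rs[0])

    def test_spearman_branch(self, rng):
        x = rng.normal(0, 1, 30)
        assert correlate(x, np.exp(x), method="spearman").r == pytest.approx(1.0)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate(np.ones(10), rng.normal(0, 1, 10))


class TestMedianSplit:
    def test_tie_at_median_goes_low(self):
        s = median_split([1.0, 2.0, 3.0])
        assert s.n_low == 2 and s.n_high == 1

    def test_even_split_without_ties(self, rng):
        s = median_split(rng.permutation(np.arange(86, dtype=float)))
        assert (s.n_low, s.n_high) == (43, 43)

    def test_partition(self, rng):
        x = rng.normal(0, 1, 57)
        s = median_split(x)
        assert s.n_low + s.n_high == 57
        assert not (s.low_index & s.high_index).any()

    def test_planted_density_size_tradeoff_detected(self):
        """Cohorts where low-density subjects have larger glomeruli should show
        the area difference across the median split."""
        rng = np.random.default_rng(6)
        n = 86
        gd = rng.normal(2.23, 0.5, n)
        area = 24_000 - 5_500 * (gd - gd.mean()) / gd.std() + rng.normal(0, 1500, n)
        df = pd.DataFrame({"mean_gd": gd, "area": area, "sex": ["m"] * n})
        res = compare_by_median_split(df, "mean_gd", ["area"])["all"]["area"]
        assert res.mean_sd[0][0] > res.mean_sd[1][0]  # low-GD group larger
        assert res.p_value < 0.05


class TestRegressionStrategy:
    def test_recovers_planted_slope(self, rng):
        n = 86
        x = rng.normal(0, 1, n)
        y = 2.0 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x})
        res = regression_strategy(df, "y", ["x"])
        eff = res.effect("x").unadjusted
        assert eff.ci_low <= 2.0 <= eff.ci_high

    def test_noise_covariate_dropped_from_full_model(self):
        rng = np.random.default_rng(7)
        kept = 0
        reps = 1000
        for _ in range(reps):
            n = 86
            x = rng.normal(0, 1, n)
            noise = rng.normal(0, 1, n)
            y = 1.5 * x + rng.normal(0, 1, n)
            df = pd.DataFrame({"y": y, "x": x, "noise": noise})
            res = regression_strategy(df, "y", ["x", "noise"])
            if "noise" not in res.selected:
                kept += 1
        assert kept / reps >= 0.93

    def test_lognormal_outcome_triggers_log_branch(self):
        rng = np.random.default_rng(8)
        n = 86
        x = rng.normal(0, 1, n)
        y = np.exp(1.0 * x + rng.normal(0, 1.0, n))
        res = regression_strategy(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        assert res.log_transformed
        assert res.residual_shapiro_p < 0.05

    def test_collinear_covariates_named(self, rng):
        n = 50
        a = rng.normal(0, 1, n)
        df = pd.DataFrame({"y": 3 * a + rng.normal(0, 0.1, n), "a": a, "b": a * 1.0000001})
        with pytest.raises(ValueError, match="'a' and 'b'"):
            regression_strategy(df, "y", ["a", "b"])
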