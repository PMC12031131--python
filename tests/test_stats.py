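from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kardia.stats import (
    correlation_matrix,
    descriptives,
    mann_whitney_u,
    posthoc_power,
    shapiro_wilk,
    significance_filter,
)


class TestDescriptives:
    def test_symmetric_triplet(self):
        d = descriptives(np.array([1.0, 2.0, 3.0]))
        assert d.mean == 2.0 and d.median == 2.0
        assert d.sd == pytest.approx(1.0)
        assert d.se == pytest.approx(0.5774, abs=1e-4)
        assert d.variance == pytest.approx(1.0)
        assert d.skewness == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_degenerate(self):
        d = descriptives(np.full(5, 3.0))
        assert d.sd == 0.0 and d.skewness == 0.0 and d.degenerate

    def test_asymmetric_triplet_against_hand_formulas(self):
        x = np.array([1.0, 1.0, 4.0])
        d = descriptives(x)
        n, mean = 3, 2.0
        sd = np.sqrt(((1 - 2.0) ** 2 * 2 + (4 - 2.0) ** 2) / (n - 1))
        m3 = np.mean((x - mean) ** 3)
        m2 = np.mean((x - mean) ** 2)
        g1 = m3 / m2**1.5
        adj = np.sqrt(n * (n - 1)) / (n - 2) * g1
        assert d.n == n and d.mean == mean and d.median == 1.0
        assert d.sd == pytest.approx(sd)
        assert d.se == pytest.approx(sd / np.sqrt(n))
        assert d.variance == pytest.approx(sd**2)
        assert d.min == 1.0 and d.max == 4.0
        assert d.skewness == pytest.approx(adj, rel=1e-12)

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            descriptives(np.array([1.0]))


class TestShapiroWilk:
    def test_normal_sample_rarely_rejected(self):
        rng = np.random.default_rng(101)
        rejections = sum(
            shapiro_wilk(rng.standard_normal(80))[1] < 0.05
            for _ in range(40)
        )
        assert rejections <= 6  # ~5% nominal rate

    def test_bimodal_sample_strongly_rejected(self):
        rng = np.random.default_rng(55)
        x = np.concatenate([rng.normal(-4, 0.3, 60), rng.normal(4, 0.3, 60)])
        w, p = shapiro_wilk(x)
        assert p < 0.001

    def test_constant_sample_is_error(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 1.0))

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))


def exhaustive_p(x, y):
    """Enumerate every group labeling of the pooled sample; two-tailed p of
    the min-U statistic (independent reimplementation for cross-checking)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, n_x = pooled.size, len(x)
    max_u = n_x * (n - n_x)
    obs_ux = np.sum(ranks[:n_x]) - n_x * (n_x + 1) / 2
    obs = min(obs_ux, max_u - obs_ux)
    hits = 0
    for combo in combinations(range(n), n_x):
        ux = ranks[list(combo)].sum() - n_x * (n_x + 1) / 2
        if min(ux, max_u - ux) <= obs + 1e-12:
            hits += 1
    return hits / comb(n, n_x)


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_u_sum_identity_and_label_swap(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 25)
        u_xy, p_xy = mann_whitney_u(x, y)
        u_yx, p_yx = mann_whitney_u(y, x)
        assert u_xy == u_yx  # min(U_x, U_y) is label-symmetric
        assert p_xy == p_yx
        assert 0 <= u_xy <= len(x) * len(y)

    @pytest.mark.parametrize("n_x,n_y", [(2, 3), (3, 3), (4, 4), (3, 6)])
    def test_exact_matches_enumeration_oracle(self, n_x, n_y, rng):
        for _ in range(3):
            x = rng.normal(0, 1, n_x)
            y = rng.normal(0.8, 1, n_y)
            u, p = mann_whitney_u(x, y, mode="exact")
            assert p == pytest.approx(exhaustive_p(x, y), abs=1e-12)

    def test_exact_matches_permutation_monte_carlo(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1.0, 1, 8)
        u_obs, p_exact = mann_whitney_u(x, y, mode="exact")
        pooled = np.concatenate([x, y])
        max_u = 64
        hits = 0
        n_perm = 100_000
        perm_rng = np.random.default_rng(999)
        ranks = sps.rankdata(pooled)
        for _ in range(n_perm):
            perm = perm_rng.permutation(16)[:8]
            ux = ranks[perm].sum() - 36
            if min(ux, max_u - ux) <= u_obs + 1e-12:
                hits += 1
        p_mc = hits / n_perm
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_exact - p_mc) < 5 * se + 1e-4

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.6, 1, 60)
        u, p = mann_whitney_u(x, y, mode="normal")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert u == min(ref.statistic, len(x) * len(y) - ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney_u([1, 2, 2], [2, 3, 4], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def textbook_partial_spearman(x, y, z):
    """Straight-line oracle: rank, residualise on ranked covariate, correlate."""
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones_like(rz), rz])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(np.corrcoef(ex, ey)[0, 1])


class TestCorrelationMatrix:
    def test_monotone_transform_gives_unit_spearman(self):
        x = np.linspace(1, 10, 30)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        rep = correlation_matrix(df, ["x", "y"], method="spearman")
        assert rep.coefficients.loc["x", "y"] == pytest.approx(1.0)

    def test_shared_age_dependence_partialed_out(self):
        rng = np.random.default_rng(21)
        age = rng.uniform(20, 70, 200)
        df = pd.DataFrame({"age": age, "x": 2.0 * age + 1.0,
                           "y": -0.5 * age + 3.0})
        rep = correlation_matrix(df, ["x", "y"], method="spearman",
                                 control=["age"])
        assert abs(rep.coefficients.loc["x", "y"]) < 0.05

    def test_matches_textbook_oracle(self, rng):
        n = 20
        df = pd.DataFrame({
            "a": rng.normal(0, 1, n),
            "b": rng.normal(0, 1, n),
            "age": rng.uniform(20, 70, n),
        })
        rep = correlation_matrix(df, ["a", "b"], method="spearman",
                                 control=["age"])
        oracle = textbook_partial_spearman(df["a"], df["b"], df["age"])
        assert rep.coefficients.loc["a", "b"] == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_partial_spearman(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        df = pd.DataFrame({
            "a": rng.normal(0, 1, n),
            "b": rng.normal(0, 1, n),
            "age": rng.uniform(20, 70, n),
        })
        df["b"] += 0.5 * df["a"]
        rep = correlation_matrix(df, ["a", "b"], method="spearman",
                                 control=["age"])
        ref = pingouin.partial_corr(df, x="a", y="b", covar="age",
                                    method="spearman")
        assert rep.coefficients.loc["a", "b"] == pytest.approx(
            float(ref["r"].iloc[0]), abs=1e-6)

    def test_symmetry_and_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (30, 4)),
                          columns=list("abcd"))
        rep = correlation_matrix(df, list("abcd"), method="pearson")
        m = rep.coefficients.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.all((m >= -1) & (m <= 1))

    def test_empty_covariate_list_reproduces_plain_coefficient(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 25),
                           "b": rng.normal(0, 1, 25)})
        plain = correlation_matrix(df, ["a", "b"], method="spearman")
        rho_ref = sps.spearmanr(df["a"], df["b"]).statistic
        assert plain.coefficients.loc["a", "b"] == pytest.approx(rho_ref,
                                                                 abs=1e-12)

    def test_zero_variance_column_flagged_nan(self, rng):
        df = pd.DataFrame({"a": np.ones(20), "b": rng.normal(0, 1, 20)})
        rep = correlation_matrix(df, ["a", "b"])
        assert np.isnan(rep.coefficients.loc["a", "b"])


class TestSignificanceFilter:
    def test_strictness_at_threshold(self):
        mask = significance_filter(np.array([0.001, 0.0009, 0.5]), alpha=0.001)
        np.testing.assert_array_equal(mask, [False, True, False])

    def test_all_ones_matrix(self):
        assert not significance_filter(np.ones((3, 3))).any()


class TestPosthocPower:
    def test_null_effect_power_equals_alpha(self):
        p = posthoc_power(5.0, 1.0, 30, 5.0, 1.0, 30, alpha=0.05)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_reference_group_statistics(self):
        """Published-style inputs: two groups with d ~ 0.64 and n = 39/85
        give ~91% achieved power at alpha 0.05 two-tailed."""
        p = posthoc_power(2.54, 1.23, 39, 1.71, 1.33, 85)
        assert 100 * p == pytest.approx(91.37, abs=1.5)

    def test_monotone_in_effect_and_n(self):
        base = posthoc_power(1.0, 1.0, 20, 0.5, 1.0, 20)
        assert posthoc_power(1.5, 1.0, 20, 0.5, 1.0, 20) > base
        assert posthoc_power(1.0, 1.0, 40, 0.5, 1.0, 40) > base
        assert posthoc_power(1.0, 1.0, 20, 0.5, 1.0, 20, alpha=0.10) > base

    def test_large_n_approaches_one(self):
        assert posthoc_power(1.0, 1.0, 5000, 0.8, 1.0, 5000) > 0.999

    def test_are_variant_slightly_lower(self):
        t = posthoc_power(2.54, 1.23, 39, 1.71, 1.33, 85)
        mw = posthoc_power(2.54, 1.23, 39, 1.71, 1.33, 85, method="mw_are")
        assert mw < t

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            posthoc_power(1.0, 0.0, 10, 0.0, 1.0, 10)
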