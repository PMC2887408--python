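from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snailguild import comparative_stats as cs


def exact_permutation_p(x, y):
    """Full enumeration oracle for the two-tailed correlation test."""
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    count = sum(
        abs(np.corrcoef(x, np.array(perm))[0, 1]) >= r_obs - 1e-12
        for perm in permutations(y)
    )
    import math

    return count / math.factorial(len(y))


class TestRandomizationCorrelation:
    def test_matches_full_enumeration_at_n4(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.2, 1.9, 3.4, 3.9])
        exact = exact_permutation_p(x, y)
        res = cs.randomization_correlation(x, y, iterations=20_000, seed=5)
        mc_se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_value - exact) < 4 * mc_se + 1e-4

    def test_perfect_correlation_near_attainable_minimum(self):
        x = np.arange(10, dtype=float)
        res = cs.randomization_correlation(x, x, iterations=100_000, seed=1)
        assert res.statistic == pytest.approx(1.0)
        # ties of |r|=1 arise only from the reversed ordering: the exact
        # two-tailed p is 2/10! ~ 5.5e-7, so the estimate sits at or near
        # the attainable floor 1/(B+1)
        assert res.p_value <= 3e-4

    def test_p_floor_and_bounds(self):
        x = np.arange(5, dtype=float)
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        res = cs.randomization_correlation(x, y, iterations=500, seed=2)
        assert 1 / 501 <= res.p_value <= 1.0

    def test_seed_change_shifts_p_only_within_mc_error(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 12))
        ps = [cs.randomization_correlation(x, y, iterations=20_000, seed=s).p_value
              for s in (1, 2, 3)]
        p0 = np.mean(ps)
        mc_se = np.sqrt(p0 * (1 - p0) / 20_000)
        assert max(ps) - min(ps) < 8 * mc_se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cs.randomization_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTwoStageRandomization:
    def test_equal_gsis_reduce_to_inverse_growth_correlation(self):
        # with constant GSIs the pseudo-RRA is a constant times
        # 1/growth, so with one seed the compound null equals a plain
        # permutation test of 1/growth against mortality
        rng = np.random.default_rng(4)
        growth = rng.uniform(5, 30, 10)
        mortality = rng.normal(size=10)
        gsi = np.full(10, 0.2)
        two = cs.two_stage_randomization(growth, mortality, gsi,
                                         iterations=5_000, seed=9)
        plain = cs.randomization_correlation(mortality, 1.0 / growth,
                                             iterations=5_000, seed=9)
        assert two.p_value == pytest.approx(plain.p_value, abs=1e-12)
        assert two.statistic == pytest.approx(plain.statistic, rel=1e-9)

    def test_detects_true_coupling(self):
        # growth genuinely falls with mortality and GSIs rise with it:
        # the observed RRA-mortality correlation must beat the null of
        # randomly re-paired growth
        rng = np.random.default_rng(6)
        mortality = np.linspace(0.0, 0.4, 10)
        growth = np.exp(3.0 - 4.0 * mortality + rng.normal(0, 0.1, 10))
        gsi = 0.15 + 0.5 * mortality + rng.normal(0, 0.01, 10)
        res = cs.two_stage_randomization(growth, mortality, gsi,
                                         iterations=20_000, seed=7)
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_null_when_growth_unrelated_to_mortality(self):
        # with growth exchangeable against mortality the compound null is
        # true even though the GSIs carry a mortality trend: p stays
        # non-extreme
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(60):
            mortality = rng.normal(0.2, 0.1, 10)
            growth = np.exp(rng.normal(2.5, 0.3, 10))
            gsi = np.clip(0.15 + 0.5 * mortality + rng.normal(0, 0.02, 10),
                          0.01, 0.9)
            ps.append(cs.two_stage_randomization(
                growth, mortality, gsi, iterations=500,
                seed=int(rng.integers(2**31))).p_value)
        # roughly uniform: around 5% of p-values below 0.05
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            cs.two_stage_randomization([1.0, -1.0, 2.0], [0.1, 0.2, 0.3],
                                       [0.1, 0.1, 0.1])


class TestSmaFit:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = cs.sma_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_negative_r_closed_form(self):
        # sd(y)/sd(x) = 2 with r < 0 must give slope -2
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = -0.5 * x + rng.normal(scale=np.sqrt(4 - 0.25), size=200)
        fit = cs.sma_fit(x, y)
        expected = -np.std(y, ddof=1) / np.std(x, ddof=1)
        assert fit.slope == pytest.approx(expected, rel=1e-12)
        assert fit.r < 0

    def test_sma_steeper_than_ols(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        sma = cs.sma_fit(x, y)
        ols = np.polyfit(x, y, 1)[0]
        assert abs(sma.slope) >= abs(ols)

    def test_symmetry_up_to_inversion(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        assert abs(cs.sma_fit(x, y).slope) == pytest.approx(
            1.0 / abs(cs.sma_fit(y, x).slope), rel=1e-9)


class TestOriginRegression:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 5.0])
        res = cs.regression_through_origin(x, 3 * x)
        assert res.slope == pytest.approx(3.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_nine_contrast_pairs_df8(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 9))
        res = cs.regression_through_origin(x, y)
        assert res.df == 8

    def test_matches_sum_formula_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=20)
        y = 1.7 * x + rng.normal(size=20)
        res = cs.regression_through_origin(x, y)
        slope = np.sum(x * y) / np.sum(x * x)
        resid = y - slope * x
        se = np.sqrt(np.sum(resid**2) / (len(x) - 1) / np.sum(x * x))
        t = slope / se
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 19), rel=1e-9)

    def test_zero_x_rejected(self):
        with pytest.raises(ValueError):
            cs.regression_through_origin([0.0, 0.0], [1.0, 2.0])


class TestPlasticity:
    def make_site_means(self, slope_by_group, seed=0, n_sites=12):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, (group, slope) in enumerate(slope_by_group.items()):
            risk = rng.uniform(0, 0.5, n_sites)
            growth = 10 + 2 * gi + slope * risk + rng.normal(0, 0.5, n_sites)
            for si in range(n_sites):
                rows.append({"group": group, "site": f"s{si}",
                             "mean_growth": growth[si], "risk": risk[si]})
        return pd.DataFrame(rows)

    def test_numerator_df_counts_groups(self):
        df = self.make_site_means({f"g{i}": 0.0 for i in range(10)})
        res = cs.plasticity_test(df)
        assert res.df_num == 10
        assert res.df_den == len(df) - 2 * 10

    def test_null_f_moderate(self):
        res = cs.plasticity_test(self.make_site_means(
            {f"g{i}": 0.0 for i in range(5)}, seed=3))
        assert res.p_value > 0.01

    def test_true_plastic_decline_detected(self):
        res = cs.plasticity_test(self.make_site_means(
            {f"g{i}": -8.0 for i in range(5)}, seed=4))
        assert res.p_value < 0.01

    def test_single_site_group_dropped(self):
        df = self.make_site_means({"a": 0.0, "b": 0.0}, n_sites=6)
        lone = pd.DataFrame([{"group": "c", "site": "s0",
                              "mean_growth": 5.0, "risk": 0.2}])
        res = cs.plasticity_test(pd.concat([df, lone], ignore_index=True))
        assert "c" not in res.groups_tested
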