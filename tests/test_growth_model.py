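import numpy as np
import pandas as pd
import pytest

from snailguild import growth_model as gm
from snailguild import synthetic_data as sd


def simple_records(groups_and_growth, sizes=None):
    """Single-site records: {group: [growth values]} with shared sizes."""
    rows = []
    for group, values in groups_and_growth.items():
        s = sizes if sizes is not None else list(range(1, len(values) + 1))
        for size, y in zip(s, values):
            rows.append({
                "site": "s1", "estuary": "E", "habitat": "channel",
                "growing_days": 94, "gender": "female", "infection": "none",
                "initial_size": float(size), "growth": float(y), "group": group,
            })
    return pd.DataFrame(rows)


class TestFitGrowth:
    def test_two_group_log_ratio(self):
        # flat responses per group: the Poisson MLE group means equal
        # the sample means, so the group coefficient is ln(8/2) = ln 4
        records = simple_records({"a": [2, 2, 2, 2], "b": [8, 8, 8, 8]})
        fit = gm.fit_growth(records, compute_term_tests=False)
        assert fit.coef("group[b]") == pytest.approx(np.log(4), abs=1e-6)

    def test_constant_response_intercept(self):
        records = simple_records({"a": [5, 5, 5, 5, 5]})
        fit = gm.fit_growth(records, compute_term_tests=False)
        assert fit.coef("intercept") == pytest.approx(np.log(5), abs=1e-8)
        assert fit.coef("initial_size") == pytest.approx(0.0, abs=1e-8)
        assert fit.dispersion == pytest.approx(0.0, abs=1e-10)

    def test_ten_groups_term_df9(self, growth_fit):
        terms = growth_fit.terms.set_index("term")
        assert terms.loc["group", "df"] == 9
        assert terms.loc["group:initial_size", "df"] == 9
        assert terms.loc["estuary", "df"] == 2
        assert terms.loc["habitat[estuary]", "df"] == 1
        assert terms.loc["site[estuary,habitat]", "df"] == 13
        assert terms.loc["growing_time[estuary]", "df"] == 2

    def test_quasi_estimates_equal_plain_poisson(self, retained_records):
        # the dispersion scales only uncertainties, never point estimates
        import statsmodels.api as sm

        fit = gm.fit_growth(retained_records, compute_term_tests=False)
        X, _, _, _ = gm._build_design(retained_records, fit.design)
        y = retained_records["growth"].to_numpy(dtype=float)
        plain = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale=1.0)
        assert np.allclose(fit.params, plain.params, atol=1e-8)

    def test_dispersion_is_pearson_chi2_over_df(self, growth_fit, retained_records):
        X, _, _, _ = gm._build_design(retained_records, growth_fit.design)
        y = retained_records["growth"].to_numpy(dtype=float)
        mu = np.exp(X @ growth_fit.params)
        pearson = float(np.sum((y - mu) ** 2 / mu))
        assert growth_fit.dispersion == pytest.approx(
            pearson / growth_fit.df_resid, rel=1e-8)

    @pytest.mark.parametrize("phi", [1.0, 4.0])
    def test_dispersion_recovery(self, phi):
        config = sd.default_config(n_snails_per_site=250, seed=17,
                                   dispersion=phi)
        world = sd.generate_world(config)
        from snailguild import pipeline as pl

        retained, _ = pl.apply_filters(world.records)
        fit = gm.fit_growth(retained, compute_term_tests=False)
        assert fit.dispersion == pytest.approx(phi, rel=0.12)

    def test_all_zero_group_rejected(self):
        records = simple_records({"a": [0, 0, 0], "b": [3, 4, 5]})
        with pytest.raises(ValueError, match="all-zero"):
            gm.fit_growth(records)

    def test_singular_design_names_alias(self):
        records = simple_records({"a": [2, 3, 4]}, sizes=[5, 5, 5])
        with pytest.raises(ValueError, match="singular"):
            gm.fit_growth(records)


class TestGrowthCurve:
    def test_constant_curve_for_zero_slope(self):
        curve = gm.GrowthCurve("a", log_intercept=np.log(7.0), size_slope=0.0,
                               domain=(0.0, 100.0), sampled_range=(0.0, 100.0))
        assert curve(3.0) == pytest.approx(7.0)
        assert curve(97.0) == pytest.approx(7.0)

    def test_negative_slope_monotone_decreasing(self, growth_fit):
        for group in growth_fit.groups:
            curve = gm.growth_curve(growth_fit, group)
            lo, hi = curve.domain
            grid = np.linspace(lo, hi, 30)
            vals = curve(grid)
            assert np.all(np.diff(vals) < 0)
            assert np.all(vals > 0)

    def test_extrapolation_rejected(self, growth_fit):
        curve = gm.growth_curve(growth_fit, growth_fit.groups[0])
        with pytest.raises(ValueError, match="domain"):
            curve(curve.domain[1] * 1.5)

    def test_unknown_group_rejected(self, growth_fit):
        with pytest.raises(ValueError):
            gm.growth_curve(growth_fit, "nosuch")

    def test_mean_size_evaluation_consistent(self, growth_fit):
        group = growth_fit.groups[3]
        curve = gm.growth_curve(growth_fit, group)
        at = growth_fit.mean_initial_size
        assert gm.growth_at_mean_size(growth_fit, group) == pytest.approx(curve(at))

    def test_curve_recovers_generating_function(self, default_world, growth_fit):
        # reference standardization is the baseline site; compare the
        # fitted group curve against the generating law with the
        # baseline site's configured effect folded in
        config = default_world.config
        baseline_site = sorted(config.site_layout["CSM"])[0]
        offset = config.site_log_effects[baseline_site]
        ref_scale = 94.0 / config.reference_days
        for group in ("female", "smcy"):
            truth = config.growth_params[group]
            curve = gm.growth_curve(growth_fit, group)
            at = 705.0
            expected = np.exp(truth.intercept + truth.slope * at + offset) * ref_scale
            assert curve(at) == pytest.approx(expected, rel=0.35)


class TestIntegral:
    def test_constant_curve_area(self):
        curve = gm.GrowthCurve("a", np.log(3.0), 0.0, (0.0, 10.0), (0.0, 10.0))
        assert gm.total_growth_allocation(curve, 2.0, 6.0) == pytest.approx(12.0)

    def test_exp_linear_closed_form(self):
        a, b = 1.3, -0.002
        curve = gm.GrowthCurve("a", a, b, (0.0, 2000.0), (0.0, 2000.0))
        lo, hi = 100.0, 1500.0
        analytic = (np.exp(a + b * hi) - np.exp(a + b * lo)) / b
        assert gm.total_growth_allocation(curve, lo, hi) == pytest.approx(
            analytic, rel=1e-9)

    def test_inverted_limits_rejected(self):
        curve = gm.GrowthCurve("a", 0.0, 0.0, (0.0, 10.0), (0.0, 10.0))
        with pytest.raises(ValueError):
            gm.total_growth_allocation(curve, 6.0, 2.0)

    def test_common_limits_average_group_ranges(self, growth_fit):
        lo, hi = gm.common_size_limits(growth_fit)
        lows, highs = zip(*growth_fit.group_size_range.values())
        assert lo == pytest.approx(np.mean(lows))
        assert hi == pytest.approx(np.mean(highs))


class TestPairwiseContrasts:
    def test_ten_groups_45_contrasts(self, growth_fit):
        table = gm.pairwise_contrasts(growth_fit)
        assert len(table) == 45
        assert {"p_value", "p_adjusted", "significant_fdr"} <= set(table.columns)

    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(21)
        y = rng.poisson(6, size=120).astype(float)
        records = simple_records({"a": y[:60], "b": y[60:]},
                                 sizes=list(np.tile(np.arange(1, 31), 2)))
        fit = gm.fit_growth(records, compute_term_tests=False)
        table = gm.pairwise_contrasts(fit, at_size=15.0)
        assert abs(table["log_ratio"].iloc[0]) < 0.2
        assert table["p_value"].iloc[0] > 0.05

    def test_fdr_no_more_liberal_than_nominal(self, growth_fit):
        table = gm.pairwise_contrasts(growth_fit)
        assert table["significant_fdr"].sum() <= table["significant_nominal"].sum()
        # BH adjusted p never falls below the raw p
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
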