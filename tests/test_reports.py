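import numpy as np
import pandas as pd
import pytest
from scipy import stats

import provgall as pg
from provgall.errors import AliasingError, ConfigurationError, ProvgallError
from provgall.glmm import PosteriorSamples
from provgall.reports import summary_ratios


def _samples(fixed, variances, family="gaussian", fpv=None):
    fixed = pd.DataFrame(fixed)
    variances = pd.DataFrame(variances)
    fpv = np.zeros(len(fixed)) if fpv is None else np.asarray(fpv, dtype=float)
    return PosteriorSamples(
        fixed=fixed, variances=variances, fixed_predictor_variance=fpv,
        family=family, spec=None, seed=0,
    )


class TestVarianceComponents:
    def test_single_term_arithmetic(self):
        n = 200
        s = _samples({"intercept": np.zeros(n)},
                     {"g": np.full(n, 3.0), "residual": np.full(n, 1.0)})
        vc = pg.variance_components(s)
        assert vc.set_index("term").loc["g", "mean"] == pytest.approx(0.75)

    def test_normalization_identity_with_rsqm_half(self):
        # sigma2_f = 2 equals the summed random variances {1, 1} -> RsqM = 0.5
        n = 200
        s = _samples({"intercept": np.zeros(n)},
                     {"a": np.ones(n), "residual": np.ones(n)},
                     fpv=np.full(n, 2.0))
        vc = pg.variance_components(s).set_index("term")
        assert vc.loc["a", "mean"] == pytest.approx(0.25)
        assert vc.loc["residual", "mean"] == pytest.approx(0.25)

    def test_per_draw_components_sum_to_one_minus_rsqm(self):
        rng = np.random.default_rng(0)
        n = 500
        s = _samples(
            {"intercept": rng.normal(0, 1, n)},
            {"a": rng.gamma(2, 1, n), "b": rng.gamma(1, 1, n),
             "residual": rng.gamma(2, 0.5, n)},
            fpv=rng.gamma(1, 1, n),
        )
        vc = pg.variance_components(s)
        rsqm, _ = pg.marginal_r2(s)
        per_draw = vc.attrs["per_draw"][["a", "b", "residual"]]
        assert np.allclose(per_draw.sum(axis=1), 1.0 - rsqm, atol=1e-6)

    def test_structured_and_nugget_pooled(self):
        n = 150
        s = _samples(
            {"intercept": np.zeros(n)},
            {"provenance_structured": np.full(n, 1.0),
             "provenance_nugget": np.full(n, 1.0),
             "residual": np.full(n, 2.0)},
        )
        vc = pg.variance_components(s).set_index("term")
        assert vc.loc["provenance", "mean"] == pytest.approx(0.5)
        assert vc.loc["provenance_structured", "mean"] == pytest.approx(0.25)

    def test_recovery_on_synthetic_fit(self, small_design):
        truth = pg.TruthParams(
            {"intercept": 0.2},
            {"provenance_structured": 0.3, "tree": 0.15, "unit": 0.35},
            seed=17,
        )
        cov = pg.identity_structure(small_design.codes)
        sim = pg.simulate_gall_counts(small_design, truth, cov, years=[2008, 2009])
        spec = pg.ModelSpec(
            "poisson_log", "count", ["year"],
            [pg.RandomTerm("provenance", "provenance", None),
             pg.RandomTerm("tree", "tree", None)],
            mcmc=pg.MCMCSchedule(8_000, 2_000, 12, seed=18),
        )
        vc = pg.variance_components(pg.fit_glmm(sim.records, spec)).set_index("term")
        total = truth.total_random_variance
        for term, sig2 in (("provenance", 0.3), ("tree", 0.15), ("unit", 0.35)):
            lo, hi = vc.loc[term, "ci_low"], vc.loc[term, "ci_high"]
            assert lo - 0.1 <= sig2 / total <= hi + 0.1


class TestMarginalR2:
    def test_intercept_only_is_zero(self):
        s = _samples({"intercept": np.ones(100)}, {"residual": np.ones(100)})
        rsqm, summary = pg.marginal_r2(s)
        assert summary["mean"] == 0.0

    def test_huge_fixed_effect_tends_to_one(self):
        s = _samples({"intercept": np.zeros(100)},
                     {"residual": np.full(100, 1e-6)},
                     fpv=np.full(100, 1e6))
        _, summary = pg.marginal_r2(s)
        assert summary["mean"] > 0.999

    def test_matches_independent_formula_on_poisson_draws(self):
        """Step-by-step Nakagawa-Schielzeth evaluation, coded separately."""
        rng = np.random.default_rng(1)
        n = 400
        b0 = rng.normal(0.5, 0.1, n)
        s = _samples(
            {"intercept": b0},
            {"g": rng.gamma(2, 0.2, n), "unit": rng.gamma(2, 0.1, n)},
            family="poisson_log",
            fpv=rng.gamma(1, 0.3, n),
        )
        rsqm, _ = pg.marginal_r2(s)
        s2r = s.variances["g"].to_numpy() + s.variances["unit"].to_numpy()
        lam = np.exp(b0 + s2r / 2.0)
        s2d = np.log(1.0 / lam + 1.0)
        oracle = s.fixed_predictor_variance / (s.fixed_predictor_variance + s2r + s2d)
        assert np.allclose(rsqm, oracle, atol=1e-12)


class TestPmcmc:
    def test_symmetric_draws_give_one(self):
        draws = np.r_[np.ones(500), -np.ones(500)]
        assert pg.pmcmc(draws) == 1.0

    def test_floor_rule(self):
        assert pg.pmcmc(np.ones(1000)) == pytest.approx(0.002)

    def test_normal_draws_match_tail_probability(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(1.0, 1.0, 100_000)
        expected = 2 * stats.norm.cdf(-1.0)
        assert pg.pmcmc(draws) == pytest.approx(expected, abs=0.01)

    def test_shifted_posterior_shrinks_pmcmc(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0.0, 1.0, 10_000)
        assert pg.pmcmc(draws + 2.0) < pg.pmcmc(draws + 1.0) < pg.pmcmc(draws)


class TestVif:
    def test_orthogonal_columns_are_one(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        v = pg.vif(X)
        assert np.allclose(v, 1.0)

    def test_duplicated_column_raises_aliasing(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(AliasingError) as err:
            pg.vif(X)
        assert set(err.value.aliased) == {"a", "b"}

    def test_weakly_correlated_traits_give_low_vifs(self, full_design):
        ph = pg.simulate_phenotypes(full_design, seed=5)
        v = pg.vif(ph[["budburst", "dbh", "form"]])
        assert (v >= 1.0).all()
        assert (v < 1.3).all()


class TestFdr:
    def test_bh_step_up_example(self):
        adj, _ = pg.fdr_adjust([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        for method in ("BH", "BY"):
            adj, _ = pg.fdr_adjust([0.03], method)
            assert adj[0] == pytest.approx(0.03)

    def test_by_dominates_bh(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1.0, 30)
        bh, _ = pg.fdr_adjust(p, "BH")
        by, _ = pg.fdr_adjust(p, "BY")
        assert np.all(by >= bh - 1e-12)

    def test_monotone_in_sorted_raw_p(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(0.001, 1.0, 25))
        adj, _ = pg.fdr_adjust(p, "BH")
        assert np.all(np.diff(adj) >= -1e-12)

    def test_domain_error(self):
        with pytest.raises(ProvgallError):
            pg.fdr_adjust([0.0, 0.5], "BH")


class TestPredictionCurve:
    def test_flat_when_no_effect_no_variance(self):
        s = _samples({"intercept": np.full(50, 1.0), "x": np.zeros(50)},
                     {"unit": np.zeros(50)}, family="poisson_log")
        curve = pg.prediction_curve(s, [0.0, 1.0, 2.0], "x")
        assert np.allclose(curve["mean"], np.e)

    def test_lognormal_correction_only(self):
        s = _samples({"intercept": np.zeros(50), "x": np.zeros(50)},
                     {"unit": np.full(50, 2.0)}, family="poisson_log")
        curve = pg.prediction_curve(s, [0.0, 3.0], "x")
        assert np.allclose(curve["mean"], np.exp(1.0))

    def test_single_draw_direct_evaluation(self):
        s = _samples({"intercept": np.zeros(100), "x": np.ones(100)},
                     {"unit": np.zeros(100)}, family="poisson_log")
        curve = pg.prediction_curve(s, [1.0], "x")
        assert curve["mean"].iloc[0] == pytest.approx(np.e)

    def test_quadratic_term_included(self):
        s = _samples(
            {"intercept": np.zeros(10), "x": np.zeros(10), "x_sq": np.full(10, -0.5)},
            {"unit": np.zeros(10)}, family="poisson_log")
        curve = pg.prediction_curve(s, [2.0], "x")
        assert curve["mean"].iloc[0] == pytest.approx(np.exp(-2.0))

    def test_extrapolation_warns(self):
        s = _samples({"intercept": np.zeros(10), "x": np.zeros(10)},
                     {"unit": np.zeros(10)}, family="poisson_log")
        with pytest.warns(UserWarning):
            pg.prediction_curve(s, [10.0], "x", observed_range=(0.0, 5.0))


class TestSurveySummaries:
    def test_small_worked_example(self):
        records = pd.DataFrame({
            "gall_type": "g", "year": 2008, "tree": "t1",
            "shoot": [1, 2, 3], "count": [0, 2, 4],
        })
        table = pg.survey_summary(records)
        row = table.per_year.iloc[0]
        assert row["total"] == 6
        assert row["mean_per_shoot"] == pytest.approx(2.0)
        assert row["incidence"] == pytest.approx(2 / 3)

    def test_zero_year_ratio_undefined(self):
        records = pd.DataFrame({
            "gall_type": "g", "year": [2008] * 2 + [2009] * 2,
            "shoot": [1, 2, 1, 2], "count": [3, 1, 0, 0],
        })
        table = pg.survey_summary(records)
        assert table.ratios["ratio_label"].iloc[0] == "–"
        assert np.isnan(table.ratios["ratio_value"].iloc[0])

    def test_published_ratio_styles(self, published_summary):
        r = summary_ratios(published_summary).set_index("gall_type")
        assert r.loc["Neuroterus anthracinus (asexual)", "ratio_label"] == "16:1"
        assert r.loc["Cynips divisa (asexual)", "ratio_label"] == "13:1"
        assert r.loc["Neuroterus albipes (sexual)", "ratio_label"] == "1:7"


class TestIncidenceFilter:
    def test_threshold_zero_excludes_nothing(self, published_summary):
        retained, excluded = pg.incidence_filter(published_summary, threshold=0.0)
        assert excluded == []

    def test_requires_rarity_in_every_year(self):
        df = pd.DataFrame({
            "gall_type": ["a", "a", "b", "b"],
            "year": [2008, 2009] * 2,
            "incidence": [0.005, 0.05, 0.005, 0.003],
        })
        retained, excluded = pg.incidence_filter(df, 0.01)
        assert retained == ["a"]
        assert excluded == ["b"]

    def test_monotone_in_threshold(self, published_summary):
        prev = set()
        for thr in (0.0, 0.001, 0.01, 0.05, 0.2):
            _, excluded = pg.incidence_filter(published_summary, thr)
            assert prev <= set(excluded)
            prev = set(excluded)


class TestCompareStructures:
    def test_single_mode_matches_direct_fit(self, small_design, smoke_schedule):
        truth = pg.TruthParams(
            {"intercept": 0.2}, {"provenance_structured": 0.3, "unit": 0.3}, seed=23
        )
        cov = pg.identity_structure(small_design.codes)
        sim = pg.simulate_gall_counts(small_design, truth, cov, years=[2008])
        table = pg.compare_structures(
            sim.records, "synthetic_gall", {"identity": cov},
            fixed_terms=[], schedule=smoke_schedule,
            include_zone=False, include_tree=False,
        )
        assert len(table) == 1
        spec = pg.standard_gall_spec(
            cov, fixed_terms=[],
            schedule=pg.MCMCSchedule(smoke_schedule.n_iter, smoke_schedule.burn_in,
                                     smoke_schedule.thin, 0),
            include_zone=False, include_tree=False)
        direct = pg.variance_components(pg.fit_glmm(sim.records, spec))
        want = direct.set_index("term").loc["provenance", "mean"]
        assert table["provenance_component"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_no_signal_reports_near_zero(self, smoke_schedule):
        design = pg.generate_origins(
            20, seed=31, trees_per_plot_surveyed=4, shoots_per_tree=4
        )
        truth = pg.TruthParams({"intercept": 0.5}, {"unit": 0.3}, seed=29)
        cov = pg.identity_structure(design.codes)
        sim = pg.simulate_gall_counts(design, truth, cov, years=[2008])
        table = pg.compare_structures(
            sim.records, "synthetic_gall", {"identity": cov},
            fixed_terms=[], schedule=smoke_schedule,
            include_zone=False, include_tree=False,
        )
        assert table["provenance_component"].iloc[0] < 0.05

    def test_empty_modes_rejected(self, small_design):
        with pytest.raises(ConfigurationError):
            pg.compare_structures(pd.DataFrame({"gall_type": ["g"], "provenance": ["a"]}),
                                  "g", {})
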