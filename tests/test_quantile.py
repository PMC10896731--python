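import warnings

import numpy as np
import pandas as pd
import pytest

from _oracles import grid_search_loss, pinball_loss_reference
from yieldgap.ingest import weighted_quantile, zscore
from yieldgap.quantile import (
    RESPONSE,
    LossConfig,
    ModelSpec,
    build_design,
    fit_annual_series,
    fit_quantile,
    fit_weighted_quantile_lp,
    lambda_penalty,
    predict_attainable,
    quantile_loss,
    under_surface_fraction,
)
from yieldgap.simulate import ScenarioConfig, generate_panel


class TestLoss:
    def test_perfect_fit_is_zero(self, rng):
        y = rng.uniform(1, 9, 20)
        assert quantile_loss(y, y, np.ones(20), 0.95) == 0.0

    def test_worked_example(self):
        # (0.95*2*2 + 0.05*1*1) / 3
        val = quantile_loss([10.0, 5.0], [8.0, 6.0], [2.0, 1.0], 0.95)
        assert val == pytest.approx(1.28333, abs=1e-5)

    def test_area_scale_invariance(self, rng):
        y, q = rng.uniform(0, 9, 30), rng.uniform(0, 9, 30)
        a = rng.uniform(1, 5, 30)
        assert quantile_loss(y, q, a, 0.9) == pytest.approx(quantile_loss(y, q, 10 * a, 0.9))

    def test_matches_definition(self, rng):
        y, q = rng.uniform(0, 9, 25), rng.uniform(0, 9, 25)
        a = rng.uniform(1, 5, 25)
        assert quantile_loss(y, q, a, 0.95) == pytest.approx(
            pinball_loss_reference(y, q, a, 0.95)
        )

    def test_zero_total_area_errors(self):
        with pytest.raises(ValueError):
            quantile_loss([1.0], [1.0], [0.0], 0.95)


class TestLambdaPenalty:
    def test_calibrated_surface_has_zero_penalty(self):
        y = np.arange(20, dtype=float)
        q = np.full(20, 18.5)  # 19 of 20 strictly below → fraction 0.95
        assert lambda_penalty(y, q, np.ones(20), 0.95, sd_y=2.0) == pytest.approx(0.0)

    def test_worked_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sd = np.std(y, ddof=1)
        val = lambda_penalty(y, np.full(4, 2.5), np.ones(4), 0.95, sd_y=sd)
        assert val == pytest.approx(1.29099 * 4 * abs(0.5 - 0.95), abs=1e-3)

    def test_surface_below_all_data(self):
        y = np.array([2.0, 3.0, 4.0])
        val = lambda_penalty(y, np.zeros(3), np.ones(3), 0.95, sd_y=1.5)
        assert val == pytest.approx(1.5 * 3 * 0.95)


class TestDesign:
    def test_intercept_only(self):
        spec = ModelSpec(("1",), protected=frozenset({"1"}))
        X = build_design(pd.DataFrame({"gdd": [1.0, 2.0]}), spec)
        np.testing.assert_array_equal(X, [[1.0], [1.0]])

    def test_product_term(self):
        spec = ModelSpec(("1", "gdd*map"), protected=frozenset({"1"}))
        X = build_design(pd.DataFrame({"gdd": [1.0], "map": [2.0]}), spec)
        assert X[0, 1] == 2.0

    def test_wheat_spec_has_vernalization_interactions(self):
        spec = ModelSpec.for_crop("wheat")
        assert "vf*gdd" in spec.terms and "vf*map" in spec.terms and "vf" in spec.terms
        assert "vf" not in ModelSpec.for_crop("default").terms

    def test_missing_covariate_named_in_error(self):
        spec = ModelSpec(("1", "pci"), protected=frozenset({"1"}))
        with pytest.raises(ValueError, match="pci"):
            build_design(pd.DataFrame({"gdd": [1.0]}), spec)

    def test_duplicate_and_missing_intercept_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(("1", "gdd", "gdd"))
        with pytest.raises(ValueError):
            ModelSpec(("gdd",))


class TestLPFit:
    def test_intercept_only_matches_weighted_percentile(self, rng):
        y = rng.normal(5, 2, 200)
        a = rng.lognormal(0, 1, 200)
        beta = fit_weighted_quantile_lp(np.ones((200, 1)), y, a, 0.95)
        assert beta[0] == pytest.approx(weighted_quantile(y, a, 0.95), abs=1e-6)

    def test_noiseless_recovery_to_1e6(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=60), rng.normal(size=60)])
        beta_true = np.array([4.0, 1.5, -0.7])
        y = X @ beta_true
        beta = fit_weighted_quantile_lp(X, y, np.ones(60), 0.95)
        np.testing.assert_allclose(beta, beta_true, atol=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_search_on_tiny_instances(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 7))
        X = np.column_stack([np.ones(n), r.normal(size=n)])
        y = r.normal(0, 1.5, n)
        a = r.uniform(0.5, 3.0, n)
        beta, diag = fit_quantile(X, y, a, LossConfig(tau=0.95, regularized=False))
        best, slack = grid_search_loss(X, y, a, 0.95)
        assert diag["loss"] <= best + 1e-9
        assert diag["loss"] >= best - slack

    def test_optimality_fraction_sandwich(self, rng):
        # at the LP optimum the weighted CDF at the surface brackets tau
        for tau in (0.5, 0.8, 0.95):
            y = rng.normal(5, 1, 300)
            a = rng.lognormal(0, 1, 300)
            X = np.column_stack([np.ones(300), rng.normal(size=300)])
            beta = fit_weighted_quantile_lp(X, y, a, tau)
            q = X @ beta
            tol = a.max() / a.sum() + 1e-8
            assert under_surface_fraction(y, q, a, strict=True) <= tau + tol
            assert under_surface_fraction(y, q, a, strict=False) >= tau - tol

    def test_shift_equivariance(self, rng):
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = rng.normal(3, 1, 80)
        a = rng.uniform(0.5, 2, 80)
        b1 = fit_weighted_quantile_lp(X, y, a, 0.95)
        b2 = fit_weighted_quantile_lp(X, y + 7.0, a, 0.95)
        assert b2[0] - b1[0] == pytest.approx(7.0, abs=1e-6)
        assert b2[1] == pytest.approx(b1[1], abs=1e-6)

    def test_agrees_with_independent_quantile_regression(self, rng):
        # cross-check against statsmodels' interior-point implementation on
        # the unweighted special case (equal areas reduce the loss to the
        # classical pinball objective)
        import statsmodels.api as sm

        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = 4 + 1.5 * X[:, 1] - 0.5 * X[:, 2] + rng.standard_t(df=5, size=n)
        ours = fit_weighted_quantile_lp(X, y, np.ones(n), 0.95)
        theirs = sm.QuantReg(y, X).fit(q=0.95, max_iter=2000).params
        np.testing.assert_allclose(ours, np.asarray(theirs), atol=5e-4)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            fit_weighted_quantile_lp(X, np.arange(10.0), np.ones(10), 0.95)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_weighted_quantile_lp(np.ones((2, 3)), np.ones(2), np.ones(2), 0.95)


class TestRegularizedFit:
    def test_regularized_objective_not_worse(self, rng):
        # Eq-2 objective (loss + λ) of the calibrated fit never exceeds the
        # plain LP solution's
        for _ in range(5):
            n = 400
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = 5 + X[:, 1] + rng.exponential(1.0, n)
            a = rng.lognormal(0, 1, n)
            sd = float(np.std(y, ddof=1))
            cfg = dict(tau=0.95, sd_y=sd)
            b_un, d_un = fit_quantile(X, y, a, LossConfig(regularized=False, **cfg))
            b_re, d_re = fit_quantile(X, y, a, LossConfig(regularized=True, **cfg))
            assert d_re["loss"] + d_re["lambda"] <= d_un["loss"] + d_un["lambda"] + 1e-9

    def test_calibration_within_one_percent_on_large_panel(self):
        cfg = ScenarioConfig(n_units=1500, seed=3)
        rec, _, _ = generate_panel(cfg)
        spec = ModelSpec.for_crop("default")
        fits = fit_annual_series(rec, spec, years=[2005])
        assert abs(fits[2005].under_fraction - 0.95) <= 0.01


class TestAnnualSeries:
    def test_three_year_panel_three_fits(self):
        cfg = ScenarioConfig(n_units=120, seed=2, year_start=1999, year_end=2001)
        rec, _, _ = generate_panel(cfg)
        spec = ModelSpec.for_crop("default")
        fits = fit_annual_series(rec, spec)
        assert sorted(fits) == [1999, 2000, 2001]
        assert all(fits[y].year == y for y in fits)

    def test_time_terms_rejected(self, small_panel):
        _, records, _, _ = small_panel
        spec = ModelSpec.for_crop("default", time_terms=True)
        with pytest.raises(ValueError, match="time"):
            fit_annual_series(records, spec)

    def test_sparse_year_skipped_with_warning(self):
        cfg = ScenarioConfig(n_units=10, seed=2, year_start=2000, year_end=2000)
        rec, _, _ = generate_panel(cfg)
        spec = ModelSpec.for_crop("default")  # 15 terms need 75 records
        with pytest.warns(UserWarning, match="skipped"):
            fits = fit_annual_series(rec, spec)
        assert fits == {}

    def test_flat_truth_gives_coefficients_inside_bootstrap_band(self):
        # time-constant generator: every year's gdd coefficient should sit
        # within the year-2000 bootstrap CI
        from yieldgap.bootstrap import bootstrap_fit, percentile_ci

        cfg = ScenarioConfig(
            n_units=250, seed=6, year_start=2000, year_end=2003,
            attainment_family="lognormal",
            scenario_mix={"ceiling_pressure_flatceiling": 1.0},
        )
        rec, _, _ = generate_panel(cfg)
        spec = ModelSpec(("1", "gdd", "map", "irr"), protected=frozenset({"1"}))
        fits = fit_annual_series(rec, spec)
        ens = bootstrap_fit(rec, spec, 2000, B=40, seed=6)
        lo, hi = percentile_ci(ens.coef[:, 1], level=0.95)
        for y, fit in fits.items():
            assert lo - 1e-9 <= fit.coef[1] <= hi + 1e-9, f"year {y} outside band"


class TestPredict:
    def test_noiseless_fixture_reproduces_ceiling(self):
        cfg = ScenarioConfig(
            n_units=200, seed=4, year_start=2000, year_end=2000, attainment_family="exact",
            scenario_mix={"steady_growth": 1.0},
            true_coefficients={"1": 6.0, "gdd": 1.2, "map": 0.8, "irr": 0.6},
        )
        rec, _, truth = generate_panel(cfg)
        spec = ModelSpec(("1", "gdd", "map", "irr"), protected=frozenset({"1"}))
        fits = fit_annual_series(rec, spec, config=LossConfig(regularized=False))
        pred = predict_attainable(fits[2000], rec)
        np.testing.assert_allclose(pred, truth.records["true_attainable"], rtol=1e-6)

    def test_zero_z_covariates_return_denormalized_intercept(self, small_panel):
        _, records, _, _ = small_panel
        spec = ModelSpec(("1", "gdd"), protected=frozenset({"1"}))
        fits = fit_annual_series(records, spec, years=[2000])
        fit = fits[2000]
        at_mean = pd.DataFrame({"gdd": [fit.factors.means["gdd"]]})
        expected = (
            fit.coef[0] * fit.factors.sds[RESPONSE] + fit.factors.means[RESPONSE]
        )
        assert predict_attainable(fit, at_mean)[0] == pytest.approx(max(expected, 0.0))

    def test_negative_prediction_floored_with_warning(self, small_panel):
        _, records, _, _ = small_panel
        spec = ModelSpec(("1", "gdd"), protected=frozenset({"1"}))
        fit = fit_annual_series(records, spec, years=[2000])[2000]
        far = pd.DataFrame({"gdd": [-1e6 if fit.coef[1] > 0 else 1e6]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation warning expected too
            pred = predict_attainable(fit, far)
        assert pred[0] == 0.0
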