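"""ML SEM engine: implied covariance, discrepancy, estimation, indices,
bootstrap, model comparison — with independent closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from nrsem.sem import (SemModel, bootstrap_fit, build_parameters, compare_models,
                       fit_indices, fit_sem, implied_covariance, ml_discrepancy,
                       _objective)


def random_pd(rng, p):
    A = rng.normal(size=(p, p))
    return A @ A.T + p * np.eye(p)


# ---------------------------------------------------------------------------
# implied covariance + discrepancy
# ---------------------------------------------------------------------------

class TestImpliedCovariance:
    def _base_params(self, data):
        model = SemModel(measurement={},
                         regressions={"y1": ["y2", "x1"], "y2": ["y1", "x2"]},
                         psi="full")
        return model, build_parameters(model, data)

    def test_identity_measurement_reduces_to_psi(self, rng):
        d = pd.DataFrame(rng.normal(size=(50, 4)), columns=["y1", "y2", "x1", "x2"])
        model, params = self._base_params(d)
        params.beta[:] = 0
        params.gamma[:] = 0
        params.phi[:] = np.eye(2)
        params.psi[:] = np.array([[2.0, 0.3], [0.3, 1.0]])
        Sigma = implied_covariance(params)
        assert np.allclose(Sigma[:2, :2], params.psi)

    def test_symmetric_to_machine_precision(self, rng):
        d = pd.DataFrame(rng.normal(size=(50, 4)), columns=["y1", "y2", "x1", "x2"])
        _, params = self._base_params(d)
        params.beta[0, 1], params.beta[1, 0] = 0.4, 0.3
        Sigma = implied_covariance(params)
        assert np.array_equal(Sigma, Sigma.T)

    def test_reciprocal_loop_matches_monte_carlo(self, rng):
        n = 100_000
        B = np.array([[0, 0.5], [0.5, 0]])
        zeta = rng.multivariate_normal([0, 0], np.eye(2), size=n)
        eta = np.linalg.solve(np.eye(2) - B, zeta.T).T
        d = pd.DataFrame(np.column_stack([eta, rng.normal(size=(n, 2))]),
                         columns=["y1", "y2", "x1", "x2"])
        model, params = self._base_params(d)
        params.beta[:] = B
        params.gamma[:] = 0
        params.phi[:] = np.eye(2)
        params.psi[:] = np.eye(2)
        Sigma = implied_covariance(params)
        emp = np.cov(eta, rowvar=False)
        mc_se = np.sqrt((Sigma[:2, :2] ** 2
                         + np.outer(np.diag(Sigma)[:2], np.diag(Sigma)[:2])) / n)
        assert np.all(np.abs(Sigma[:2, :2] - emp) < 3 * mc_se)


class TestDiscrepancy:
    def test_zero_iff_sigma_equals_s(self, rng):
        for _ in range(20):
            S = random_pd(rng, 4)
            F, chi2 = ml_discrepancy(S, S.copy(), n=100)
            assert 0.0 <= F <= 1e-12 and chi2 <= 1e-10
            Sigma = random_pd(rng, 4)
            F2, _ = ml_discrepancy(S, Sigma, n=100)
            if not np.allclose(S, Sigma):
                assert F2 > 0

    def test_scalar_closed_form(self):
        F, _ = ml_discrepancy(np.array([[2.0]]), np.array([[1.0]]), n=10)
        assert F == pytest.approx(1 - np.log(2), abs=1e-12)


def test_analytic_gradient_matches_finite_differences(rng):
    n = 300
    f = rng.normal(size=n)
    d = pd.DataFrame({
        "a1": f + rng.normal(0, .7, n), "a2": .8 * f + rng.normal(0, .7, n),
        "a3": .6 * f + rng.normal(0, .7, n), "x": rng.normal(size=n),
        "y": .5 * f + rng.normal(size=n)})
    model = SemModel(measurement={"fac": ["a1", "a2", "a3"]},
                     regressions={"y": ["fac", "x"]}, psi="full")
    params = build_parameters(model, d)
    S = np.cov(d[model.observed].to_numpy(float), rowvar=False, ddof=1)
    x0 = params.pack() + rng.normal(0, 0.05, params.q)
    _, g = _objective(x0, params, S)
    num = np.zeros_like(g)
    for i in range(len(x0)):
        e = np.zeros_like(x0)
        e[i] = 1e-6
        fp, _ = _objective(x0 + e, params, S)
        fm, _ = _objective(x0 - e, params, S)
        num[i] = (fp - fm) / 2e-6
    assert np.max(np.abs(g - num)) < 1e-6


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

class TestFit:
    def test_saturated_model_reaches_perfect_fit(self):
        g = np.random.default_rng(8)
        n = 400
        x = g.normal(size=n)
        y = 0.5 * x + g.normal(size=n)
        d = pd.DataFrame({"y": y, "x": x})
        fit = fit_sem(SemModel(measurement={}, regressions={"y": ["x"]}), d)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-4)
        assert fit.cfi == pytest.approx(1.0, abs=1e-9)
        assert fit.rmsea is None

    def test_row_order_is_irrelevant(self, rng, survey_table):
        cols = ["phq1", "phq2", "phq3", "gad1", "gad2", "gad3"]
        d = survey_table[cols].astype(float)
        model = SemModel(measurement={"dep": cols[:3], "anx": cols[3:]})
        a = fit_sem(model, d)
        b = fit_sem(model, d.sample(frac=1.0, random_state=3).reset_index(drop=True))
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k], abs=1e-6)

    def test_chi2_at_truth_follows_reference_distribution(self):
        # correctly specified one-factor model: chi2 ~ chi2(df)
        rng = np.random.default_rng(1)
        chis, dfs = [], None
        for _ in range(200):
            n = 300
            f = rng.normal(size=n)
            d = pd.DataFrame({f"i{j}": lam * f + rng.normal(0, .6, n)
                              for j, lam in enumerate([1.0, .8, .7, .6])})
            fit = fit_sem(SemModel(measurement={"fac": list(d.columns)}), d)
            chis.append(fit.chi2)
            dfs = fit.df
        assert dfs == 2
        assert np.mean(chis) == pytest.approx(dfs, rel=0.10)


class TestCrossImplementationOracles:
    """ML estimates versus independent closed-form solutions.

    For saturated structural models the ML solution is an explicit function
    of the sample moments (indirect least squares / OLS); for the
    just-identified one-factor model it is the classic tetrad-style closed
    form.  Agreement: coefficients within 0.01, chi-square within 1.0.
    """

    def test_reciprocal_loop_equals_indirect_least_squares(self, rng):
        n = 1500
        x = rng.normal(size=(n, 2))
        zeta = rng.multivariate_normal([0, 0], [[.6, .2], [.2, .6]], size=n)
        B = np.array([[0, .45], [.35, 0]])
        G = np.diag([.7, .6])
        Y = np.linalg.solve(np.eye(2) - B, G @ x.T + zeta.T).T
        d = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1], "x1": x[:, 0], "x2": x[:, 1]})
        fit = fit_sem(SemModel(measurement={},
                               regressions={"y1": ["y2", "x1"], "y2": ["y1", "x2"]},
                               psi="full"), d)
        S = np.cov(d[["y1", "y2", "x1", "x2"]].to_numpy().T, ddof=1)
        Pi = S[:2, 2:] @ np.linalg.inv(S[2:, 2:])
        b12, b21 = Pi[0, 1] / Pi[1, 1], Pi[1, 0] / Pi[0, 0]
        assert fit.estimates["y1~y2"] == pytest.approx(b12, abs=0.01)
        assert fit.estimates["y2~y1"] == pytest.approx(b21, abs=0.01)
        assert fit.estimates["y1~x1"] == pytest.approx(Pi[0, 0] - b12 * Pi[1, 0], abs=0.01)
        assert fit.estimates["y2~x2"] == pytest.approx(Pi[1, 1] - b21 * Pi[0, 1], abs=0.01)
        assert abs(fit.chi2) < 1.0

    def test_recursive_chain_equals_equationwise_ols(self, rng):
        n = 1200
        x = rng.normal(size=n)
        y1 = .6 * x + rng.normal(size=n)
        y2 = .5 * y1 + .2 * x + rng.normal(size=n)
        d = pd.DataFrame({"x": x, "y1": y1, "y2": y2})
        fit = fit_sem(SemModel(measurement={},
                               regressions={"y1": ["x"], "y2": ["y1", "x"]},
                               psi="diag"), d)
        o1 = sm.OLS(y1, sm.add_constant(x)).fit()
        o2 = sm.OLS(y2, sm.add_constant(np.column_stack([y1, x]))).fit()
        assert fit.estimates["y1~x"] == pytest.approx(o1.params[1], abs=0.01)
        assert fit.estimates["y2~y1"] == pytest.approx(o2.params[1], abs=0.01)
        assert fit.estimates["y2~x"] == pytest.approx(o2.params[2], abs=0.01)
        assert abs(fit.chi2) < 1.0

    def test_seemingly_unrelated_with_common_regressors_equals_ols(self, rng):
        n = 1000
        x = rng.normal(size=(n, 2))
        E = rng.multivariate_normal([0, 0], [[1, .4], [.4, 1]], size=n)
        y1 = .5 * x[:, 0] - .3 * x[:, 1] + E[:, 0]
        y2 = .2 * x[:, 0] + .6 * x[:, 1] + E[:, 1]
        d = pd.DataFrame({"y1": y1, "y2": y2, "x1": x[:, 0], "x2": x[:, 1]})
        fit = fit_sem(SemModel(measurement={},
                               regressions={"y1": ["x1", "x2"], "y2": ["x1", "x2"]},
                               psi="full"), d)
        for out, y in (("y1", y1), ("y2", y2)):
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            assert fit.estimates[f"{out}~x1"] == pytest.approx(ols.params[1], abs=0.01)
            assert fit.estimates[f"{out}~x2"] == pytest.approx(ols.params[2], abs=0.01)
        assert abs(fit.chi2) < 1.0

    def test_one_factor_three_indicators_closed_form(self, rng):
        n = 2000
        f = rng.normal(size=n)
        d = pd.DataFrame({"i1": f + rng.normal(0, .5, n),
                          "i2": .8 * f + rng.normal(0, .5, n),
                          "i3": .6 * f + rng.normal(0, .5, n)})
        fit = fit_sem(SemModel(measurement={"fac": ["i1", "i2", "i3"]}), d)
        S = np.cov(d.to_numpy().T, ddof=1)
        phi = S[0, 1] * S[0, 2] / S[1, 2]
        lam2, lam3 = S[1, 2] / S[0, 2], S[1, 2] / S[0, 1]
        assert fit.estimates["fac=~i2"] == pytest.approx(lam2, abs=0.01)
        assert fit.estimates["fac=~i3"] == pytest.approx(lam3, abs=0.01)
        assert fit.estimates["phi[fac,fac]"] == pytest.approx(phi, abs=0.01)
        assert abs(fit.chi2) < 1.0
        assert fit.df == 0

    def test_mediation_chain_equals_ols(self, rng):
        n = 1500
        x = rng.normal(size=n)
        m = .7 * x + rng.normal(size=n)
        y = .4 * m + rng.normal(size=n)
        d = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_sem(SemModel(measurement={},
                               regressions={"m": ["x"], "y": ["m"]},
                               psi="diag"), d)
        a = sm.OLS(m, sm.add_constant(x)).fit().params[1]
        b = sm.OLS(y, sm.add_constant(m)).fit().params[1]
        assert fit.estimates["m~x"] == pytest.approx(a, abs=0.01)
        assert fit.estimates["y~m"] == pytest.approx(b, abs=0.01)


# ---------------------------------------------------------------------------
# fit indices and comparison
# ---------------------------------------------------------------------------

class TestFitIndices:
    def test_chi2_equal_df_gives_floor_rmsea_and_ceiling_cfi(self):
        idx = fit_indices(100.0, 100, 5000.0, 120, n=1000, q=30)
        assert idx["rmsea"] == 0.0 and idx["cfi"] == 1.0

    def test_worked_arithmetic(self):
        idx = fit_indices(260.0, 100, 14000.0, 120, n=1373, q=55)
        assert idx["rmsea"] == pytest.approx(np.sqrt(160 / 137200), abs=1e-10)
        assert idx["cfi"] == pytest.approx(1 - 160 / 13880, abs=1e-10)
        assert idx["cmin_df"] == pytest.approx(2.6)
        assert idx["aic"] == pytest.approx(260 + 110)

    def test_degenerate_baseline_handled_without_division_errors(self):
        idx = fit_indices(50.0, 40, 50.0, 40, n=500, q=10)
        assert idx["cfi"] == 1.0 or 0 <= idx["cfi"] <= 1

    def test_zero_df_reports_undefined_tli_rmsea(self):
        idx = fit_indices(0.0, 0, 900.0, 10, n=500, q=10)
        assert idx["rmsea"] is None and idx["cmin_df"] is None


class TestBootstrapAndComparison:
    @pytest.fixture(scope="class")
    def small_fit(self):
        rng = np.random.default_rng(12)
        n = 400
        x = rng.normal(size=n)
        y = .5 * x + rng.normal(size=n)
        z = .3 * y + rng.normal(size=n)
        d = pd.DataFrame({"x": x, "y": y, "z": z})
        model = SemModel(measurement={}, regressions={"y": ["x"], "z": ["y"]},
                         psi="diag")
        return model, d, fit_sem(model, d)

    def test_same_seed_gives_identical_cis(self, small_fit):
        model, d, fit = small_fit
        b1 = bootstrap_fit(model, d, n_boot=50, seed=4, fit=fit)
        b2 = bootstrap_fit(model, d, n_boot=50, seed=4, fit=fit)
        assert b1.ci_low == b2.ci_low and b1.ci_high == b2.ci_high

    def test_single_replicate_is_flagged_degenerate(self, small_fit):
        model, d, fit = small_fit
        with pytest.warns(UserWarning, match="degenerate"):
            b = bootstrap_fit(model, d, n_boot=1, seed=1, fit=fit)
        assert b.ci_low == b.ci_high

    def test_point_estimate_inside_percentile_ci_for_most_parameters(self, small_fit):
        model, d, fit = small_fit
        b = bootstrap_fit(model, d, n_boot=200, seed=2, fit=fit)
        inside = [b.ci_low[k] <= fit.estimates[k] <= b.ci_high[k]
                  for k in fit.estimates]
        assert np.mean(inside) >= 0.95

    def test_aic_ranking_selects_parsimonious_adequate_model(self, small_fit):
        model, d, fit = small_fit
        wrong = SemModel(measurement={}, regressions={"y": ["x"], "z": ["x"]},
                         psi="diag")
        fits = {"true": fit, "over_pruned": fit_sem(wrong, d)}
        tab = compare_models(fits)
        assert tab.loc[tab["selected"], "model"].iloc[0] == "true"

    def test_identical_models_tie_on_aic(self, small_fit):
        model, d, fit = small_fit
        tab = compare_models({"a": fit, "b": fit})
        assert tab["aic"].iloc[0] == tab["aic"].iloc[1]

    def test_different_sample_sizes_are_not_comparable(self, small_fit):
        model, d, fit = small_fit
        other = fit_sem(model, d.iloc[:300])
        with pytest.raises(ValueError, match="sample sizes"):
            compare_models({"a": fit, "b": other})


def test_true_model_wins_aic_in_most_replications(rng):
    wins = 0
    for _ in range(60):
        n = 500
        x = rng.normal(size=n)
        y = .5 * x + rng.normal(size=n)
        z = .4 * y + rng.normal(size=n)
        d = pd.DataFrame({"x": x, "y": y, "z": z})
        true = fit_sem(SemModel(measurement={},
                                regressions={"y": ["x"], "z": ["y"]}, psi="diag"), d)
        pruned = fit_sem(SemModel(measurement={},
                                  regressions={"y": ["x"], "z": ["x"]}, psi="diag"), d)
        wins += true.aic < pruned.aic
    assert wins / 60 >= 0.9
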