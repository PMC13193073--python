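"""Spatial statistics: weights against brute-force oracles, Moran's I against
the double-sum formula, OLS against normal equations, and spatial-error ML
against its own likelihood and simulation truth."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from soil2bio.spatial import (
    SpatialErrorModel,
    ci_percent,
    correlation_screen,
    fit_ols,
    fit_sem,
    knn_weights,
    morans_i,
    percent_change,
    screen_and_fit,
    variance_inflation,
)


class TestKnnWeights:
    def test_collinear_three_points_k1(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        w = knn_weights(pts, k=1)
        # endpoints pick the middle; middle picks the nearer endpoint
        assert w.neighbors[0, 0] == 1
        assert w.neighbors[1, 0] == 0
        assert w.neighbors[2, 0] == 1

    def test_row_standardization_and_no_self(self, rng):
        pts = rng.uniform(0, 100, (50, 2))
        w = knn_weights(pts, k=4)
        rowsum = np.asarray(w.W.sum(axis=1)).ravel()
        assert np.abs(rowsum - 1.0).max() < 1e-12
        assert w.W.diagonal().sum() == 0.0

    def test_agrees_with_brute_force_sort(self, rng):
        pts = rng.uniform(0, 1000, (500, 2))
        w = knn_weights(pts, k=3)
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        brute = np.argsort(d, axis=1)[:, :3]
        assert np.array_equal(np.sort(w.neighbors, axis=1), np.sort(brute, axis=1))

    def test_duplicates_jittered_and_k_validated(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        w = knn_weights(pts, k=1)
        assert np.abs(np.asarray(w.W.sum(axis=1)).ravel() - 1).max() < 1e-12
        with pytest.raises(ValueError):
            knn_weights(pts, k=3)


class TestMoransI:
    def test_brute_force_formula_agreement(self, rng):
        pts = rng.uniform(0, 100, (60, 2))
        w = knn_weights(pts, k=3)
        r = rng.normal(0, 1, 60)
        got = morans_i(r, w)
        Wd = w.W.toarray()
        z = r - r.mean()
        num = sum(Wd[i, j] * z[i] * z[j] for i in range(60) for j in range(60))
        want = (60 / Wd.sum()) * num / (z @ z)
        assert got.I == pytest.approx(want, abs=1e-12)

    def test_iid_residuals_rarely_significant(self, rng):
        pts = rng.uniform(0, 1000, (200, 2))
        w = knn_weights(pts, k=1)
        hits = sum(
            abs(morans_i(np.random.default_rng(s).normal(0, 1, 200), w).z) > 1.96
            for s in range(100)
        )
        assert hits <= 12  # ~5% nominal

    def test_smooth_function_of_coordinates_detected(self, rng):
        pts = rng.uniform(0, 1000, (150, 2))
        w = knn_weights(pts, k=2)
        r = np.sin(pts[:, 0] / 300) + pts[:, 1] / 1000
        m = morans_i(r, w)
        assert m.I > 0 and m.p < 0.01

    def test_permutation_p_agrees_with_analytic_in_clear_cases(self, rng):
        pts = rng.uniform(0, 1000, (120, 2))
        w = knn_weights(pts, k=2)
        smooth = np.sin(pts[:, 0] / 300) + pts[:, 1] / 1000
        assert morans_i(smooth, w, permutations=199).p < 0.01
        noise = rng.normal(0, 1, 120)
        assert morans_i(noise, w, permutations=199).p > 0.05

    def test_zero_variance_rejected(self, rng):
        w = knn_weights(rng.uniform(0, 10, (20, 2)), k=1)
        with pytest.raises(ValueError):
            morans_i(np.ones(20), w)


class TestOls:
    def test_exact_linear_fit(self, rng):
        X = rng.normal(0, 1, (50, 2))
        y = 1.0 + X @ [2.0, -1.0]
        fit = fit_ols(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert np.abs(fit.resid).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(0, 1, (80, 3))
        y = rng.normal(0, 1, 80)
        fit = fit_ols(y, X)
        Xm = np.column_stack([np.ones(80), X])
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        assert np.abs(fit.params.to_numpy() - beta).max() < 1e-10

    def test_rank_deficiency_reports_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 30)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(rng.normal(0, 1, 30), X)

    def test_default_covariates_have_low_vif(self, cohort):
        cols = ["ses_score", "bmi_percentile", "age", "hei_fruit", "vacancy_pct",
                "dist_highway_m", "max_temp_c", "race", "gender", "parent_smokes"]
        vif = variance_inflation(cohort[cols])
        assert (vif < 2.0).all(), vif


class TestSpatialErrorModel:
    def _simulate(self, n, lam, seed, beta=(0.5, -0.3), sigma=0.4):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, (n, 2))
        w = knn_weights(pts, k=1)
        X = rng.standard_normal((n, len(beta)))
        e = rng.normal(0, sigma, n)
        u = np.linalg.solve(np.eye(n) - lam * w.W.toarray(), e) if lam else e
        y = 1.0 + X @ np.asarray(beta) + u
        return y, X, w, pts

    def test_lambda_zero_data_reduces_to_ols(self):
        lams, dbeta = [], []
        for s in range(25):
            y, X, w, _ = self._simulate(281, 0.0, 500 + s)
            m = SpatialErrorModel().fit(X, y, weights=w)
            ols = fit_ols(y, X)
            lams.append(m.lambda_)
            dbeta.append(np.abs(m.params_.to_numpy() - ols.params.to_numpy()).max())
        assert abs(np.median(lams)) < 0.1
        assert np.median(dbeta) < 0.05

    def test_recovers_moderate_lambda(self):
        vals = []
        for s in range(10):
            y, X, w, _ = self._simulate(281, 0.6, 700 + s)
            vals.append(SpatialErrorModel().fit(X, y, weights=w).lambda_)
        assert 0.4 < np.mean(vals) < 0.75

    def test_likelihood_at_optimum_no_worse_than_lambda_zero(self):
        for s in range(5):
            y, X, w, _ = self._simulate(150, 0.5, 900 + s)
            m = SpatialErrorModel().fit(X, y, weights=w)
            assert m.llf_ >= m.llf_lam0_ - 1e-9

    def test_zero_weights_matrix_reproduces_ols(self, rng):
        y = rng.normal(0, 1, 60)
        X = rng.normal(0, 1, (60, 2))
        W0 = sp.csr_matrix((60, 60))
        fit = fit_sem(y, X, W0)
        ols = fit_ols(y, X)
        assert np.abs(fit.params.to_numpy() - ols.params.to_numpy()).max() < 1e-8

    def test_sklearn_param_interface(self):
        m = SpatialErrorModel(k=2)
        assert m.get_params()["k"] == 2
        m.set_params(k=3)
        assert m.k == 3


class TestScreenAndFit:
    def test_autocorrelated_errors_route_to_sem(self, rng):
        n = 200
        pts = rng.uniform(0, 1000, (n, 2))
        w = knn_weights(pts, k=1)
        X = rng.standard_normal((n, 2))
        e = np.random.default_rng(1).normal(0, 0.3, n)
        u = np.linalg.solve(np.eye(n) - 0.7 * w.W.toarray(), e)
        fit = screen_and_fit(X @ [0.5, 0.2] + u, X, pts)
        assert fit.method == "SEM" and fit.moran is not None

    def test_iid_errors_route_to_ols_about_80pct(self):
        ols_count = 0
        runs = 60
        for s in range(runs):
            rng = np.random.default_rng(3000 + s)
            pts = rng.uniform(0, 1000, (150, 2))
            X = rng.standard_normal((150, 2))
            y = X @ [0.5, 0.2] + rng.normal(0, 0.5, 150)
            ols_count += screen_and_fit(y, X, pts, p_threshold=0.2).method == "OLS"
        assert 0.65 <= ols_count / runs <= 0.95

    def test_threshold_one_always_sem(self, rng):
        pts = rng.uniform(0, 1000, (80, 2))
        X = rng.standard_normal((80, 2))
        y = X @ [0.5, 0.2] + rng.normal(0, 0.5, 80)
        assert screen_and_fit(y, X, pts, p_threshold=1.0).method == "SEM"


class TestEffectTransforms:
    def test_printed_percent_examples(self):
        assert round(percent_change(0.203), 1) == 22.5
        assert round(percent_change(0.039), 2) == 3.98
        assert percent_change(0.0) == 0.0

    def test_printed_ci_bound(self):
        lo, hi = ci_percent(0.039, 0.019, level=0.95)
        assert round(hi, 1) == 7.9

    def test_monotone_and_asymmetric(self):
        b = np.linspace(-1, 1, 101)
        pc = [percent_change(x) for x in b]
        assert all(a < c for a, c in zip(pc, pc[1:]))
        assert percent_change(0.5) != -percent_change(-0.5)

    def test_invalid_se_or_level_rejected(self):
        with pytest.raises(ValueError):
            ci_percent(0.1, 0.0)
        with pytest.raises(ValueError):
            ci_percent(0.1, 0.1, level=0.8)


class TestCorrelationScreen:
    def _tables(self, rng, n=234, rho=0.0):
        x = rng.lognormal(4, 1, n)
        noise = rng.lognormal(0, 1, n)
        y = np.exp(rho * np.log(x) + (1 - rho) * np.log(noise))
        expo = pd.DataFrame({"participant_id": np.arange(n), "method": "OK", "value": x})
        bio = pd.DataFrame({"participant_id": np.arange(n), "bm": y})
        return expo, bio

    def test_perfect_loglinear_correlation(self, rng):
        expo, bio = self._tables(rng, rho=1.0)
        bio["bm"] = expo["value"] ** 2.0
        r, p = correlation_screen(expo, bio)
        assert r.loc["OK", "bm"] == pytest.approx(1.0)

    def test_independent_pairs_small_r(self):
        rs = []
        for s in range(60):
            expo, bio = self._tables(np.random.default_rng(s))
            r, _ = correlation_screen(expo, bio)
            rs.append(abs(r.loc["OK", "bm"]))
        # null |r| at n=234: SD ~0.066, so ~95% of draws below 0.13
        assert np.mean(np.asarray(rs) < 0.13) >= 0.85

    def test_matches_covariance_formula_oracle(self, rng):
        expo, bio = self._tables(rng, rho=0.5)
        r, _ = correlation_screen(expo, bio)
        lx, ly = np.log(expo["value"]), np.log(bio["bm"])
        want = np.cov(lx, ly, ddof=1)[0, 1] / (lx.std(ddof=1) * ly.std(ddof=1))
        assert r.loc["OK", "bm"] == pytest.approx(want, abs=1e-12)

    def test_insufficient_pairs_missing(self, rng):
        expo, bio = self._tables(rng, n=5)
        r, _ = correlation_screen(expo, bio)
        assert np.isnan(r.loc["OK", "bm"])
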