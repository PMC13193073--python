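"""Interpolation oracles: dense-solve kriging checks, barycentric arithmetic,
quartile-split rules, and cross-validated method comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.dummy import DummyRegressor

from soil2bio.interpolation import (
    CombinedTINOK,
    OrdinaryKriging,
    TINInterpolator,
    VariogramModel,
    combined_tin_ok,
    cv_rmse,
    fit_variogram,
    select_best_method,
    split_outliers,
)
from soil2bio.simulate import BackgroundParams, SimulationTruth, generate_soil_field


def _df(xy, vals):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"sample_id": np.arange(len(xy)), "x": xy[:, 0],
                         "y": xy[:, 1], "metal": "Pb",
                         "concentration": np.asarray(vals, dtype=float)})


# ---------------------------------------------------------------------------
# variogram
# ---------------------------------------------------------------------------

class TestVariogram:
    def test_model_validation_and_monotonicity(self):
        with pytest.raises(ValueError):
            VariogramModel("exponential", nugget=-1)
        with pytest.raises(ValueError):
            VariogramModel("nope")
        m = VariogramModel("spherical", nugget=0.5, partial_sill=2.0, range_m=100.0)
        h = np.linspace(1, 500, 200)
        g = m(h)
        assert (np.diff(g) >= -1e-12).all() and (g >= 0).all()

    def test_white_noise_fits_mostly_nugget(self, domain):
        ratios = []
        for s in range(10):
            rng = np.random.default_rng(s)
            xy = rng.uniform(0, 2000, (300, 2))
            v = rng.normal(50, 5, 300)
            m = fit_variogram((xy, v))
            ratios.append(m.partial_sill / max(m.nugget, 1e-12))
        assert np.median(ratios) <= 0.2

    def test_range_recovery_within_factor_two(self, domain):
        # field simulated with 500 m range; median recovered range in [250, 1000]
        recovered = []
        for s in range(20):
            t = SimulationTruth(seed=3000 + s, outlier_fraction=0.0,
                                background_params=BackgroundParams(4.0, 1.0, 500.0))
            df = generate_soil_field(domain, 1000, t)
            m = fit_variogram((df[["x", "y"]].to_numpy(), np.log(df["concentration"])))
            recovered.append(m.range_m)
        med = np.median(recovered)
        assert 250.0 <= med <= 1000.0, med

    def test_constant_field_degenerates_to_pure_nugget(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, (40, 2))
        with pytest.warns(UserWarning, match="pure-nugget"):
            m = fit_variogram((xy, np.full(40, 7.0)))
        assert m.partial_sill == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_variogram((np.zeros((10, 2)), np.zeros(10)))


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

VG = VariogramModel("exponential", nugget=0.0, partial_sill=25.0, range_m=600.0)


class TestOrdinaryKriging:
    def test_exact_interpolator_with_zero_nugget(self, rng):
        X = rng.uniform(0, 1000, (50, 2))
        y = rng.uniform(10, 100, 50)
        ok = OrdinaryKriging(variogram=VG).fit(X, y)
        pred, var = ok.predict(X, return_variance=True)
        assert np.abs(pred - y).max() < 1e-8
        assert var.max() < 1e-8

    def test_constant_field_predicts_constant(self, rng):
        X = rng.uniform(0, 1000, (30, 2))
        ok = OrdinaryKriging(variogram=VG).fit(X, np.full(30, 3.5))
        assert np.allclose(ok.predict(rng.uniform(0, 1000, (20, 2))), 3.5)

    def test_weights_sum_to_one(self, rng):
        X = rng.uniform(0, 1000, (100, 2))
        y = rng.uniform(0, 50, 100)
        ok = OrdinaryKriging(variogram=VG, max_neighbors=12).fit(X, y)
        _, wsum = ok.predict(rng.uniform(0, 1000, (200, 2)), return_weights=True)
        assert np.abs(wsum - 1.0).max() < 1e-10

    def test_five_point_toy_matches_dense_solve_oracle(self):
        # direct full-covariance solve, no neighbor truncation
        X = np.array([[0, 0], [100, 0], [0, 100], [100, 100], [40, 60]], dtype=float)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        targets = np.array([[50, 50], [20, 80], [90, 10]], dtype=float)
        ok = OrdinaryKriging(variogram=VG, max_neighbors=5).fit(X, y)
        pred = ok.predict(targets)

        for t, p in zip(targets, pred):
            n = len(X)
            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = VG(cdist(X, X))
            A[n, :n] = A[:n, n] = 1.0
            b = np.append(VG(np.hypot(X[:, 0] - t[0], X[:, 1] - t[1])), 1.0)
            w = np.linalg.solve(A, b)[:n]
            assert p == pytest.approx(w @ y, abs=1e-8)

    def test_duplicate_locations_averaged_not_singular(self):
        X = np.array([[0, 0], [0, 0], [100, 0], [0, 100]], dtype=float)
        y = np.array([2.0, 4.0, 6.0, 8.0])
        ok = OrdinaryKriging(variogram=VG).fit(X, y)
        assert ok.predict(np.array([[0.0, 0.0]]))[0] == pytest.approx(3.0, abs=1e-8)

    def test_nonfinite_targets_rejected(self, rng):
        X = rng.uniform(0, 100, (20, 2))
        ok = OrdinaryKriging(variogram=VG).fit(X, rng.uniform(0, 1, 20))
        with pytest.raises(ValueError):
            ok.predict(np.array([[np.nan, 0.0]]))


# ---------------------------------------------------------------------------
# TIN
# ---------------------------------------------------------------------------

class TestTIN:
    def test_affine_field_reproduced_inside_hull(self, rng):
        X = rng.uniform(0, 100, (60, 2))
        y = 2 * X[:, 0] + 3 * X[:, 1] + 1
        tin = TINInterpolator().fit(X, y)
        t = rng.uniform(25, 75, (100, 2))
        assert np.abs(tin.predict(t) - (2 * t[:, 0] + 3 * t[:, 1] + 1)).max() < 1e-9

    def test_vertex_value_exact(self):
        X = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        y = np.array([1.0, 2.0, 3.0])
        tin = TINInterpolator().fit(X, y)
        assert np.allclose(tin.predict(X), y)

    def test_centroid_barycentric_average(self):
        X = np.array([[0, 0], [9, 0], [0, 9]], dtype=float)
        y = np.array([0.0, 0.0, 3.0])
        tin = TINInterpolator().fit(X, y)
        assert tin.predict(np.array([[3.0, 3.0]]))[0] == pytest.approx(1.0, abs=1e-12)

    def test_outside_hull_nearest_fallback_flagged(self):
        X = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        y = np.array([1.0, 2.0, 3.0])
        tin = TINInterpolator().fit(X, y)
        z, outside = tin.predict(np.array([[100.0, 100.0]]), return_outside_mask=True)
        assert outside[0] and z[0] in y

    def test_collinear_points_rejected(self):
        X = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            TINInterpolator().fit(X, np.arange(4.0))


# ---------------------------------------------------------------------------
# outlier split + combined variants
# ---------------------------------------------------------------------------

class TestSplitAndCombined:
    def test_upper_fence_quartile_arithmetic(self):
        vals = np.array(list(range(1, 10)) + [100.0])
        bulk, out = split_outliers(vals)
        assert list(vals[out]) == [100.0]
        assert out.sum() + bulk.sum() == len(vals)

    def test_symmetric_clean_data_no_outliers(self, rng):
        _, out = split_outliers(rng.uniform(0, 1, 100))
        assert out.sum() == 0

    def test_two_sided_flag_catches_low_tail(self):
        vals = np.array([-100.0] + list(range(1, 10)), dtype=float)
        _, out_one = split_outliers(vals)
        _, out_two = split_outliers(vals, two_sided=True)
        assert out_one.sum() == 0 and vals[out_two].tolist() == [-100.0]

    def test_split_with_no_outliers_equals_plain_ok(self, rng):
        X = rng.uniform(0, 1000, (60, 2))
        y = rng.uniform(40, 60, 60)  # no Tukey outliers
        t = rng.uniform(100, 900, (40, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comb = CombinedTINOK(variant="split", variogram=VG).fit(X, y)
            ok = OrdinaryKriging(variogram=VG).fit(X, y)
        assert comb.fallback_
        assert np.allclose(comb.predict(t), ok.predict(t))

    def test_full_variant_doubles_constant_field(self, rng):
        X = rng.uniform(0, 1000, (40, 2))
        y = np.full(40, 7.0)
        t = rng.uniform(100, 900, (20, 2))
        with pytest.warns(UserWarning, match="constant field"):
            pred = combined_tin_ok(_df(X, y), t, variant="full", variogram=VG)
        assert np.allclose(pred, 14.0)

    def test_log_split_matches_step_by_step_oracle(self, rng):
        X = rng.uniform(0, 1000, (80, 2))
        y = np.exp(rng.normal(3, 0.5, 80))
        y[:6] = y.max() * np.array([20, 25, 30, 35, 40, 45])  # heavy upper tail
        t = rng.uniform(100, 900, (30, 2))
        comb = CombinedTINOK(variant="log_split", variogram=VG).fit(X, y)
        pred = comb.predict(t)

        bulk, out = split_outliers(y)
        tin_part = TINInterpolator(outside="zero").fit(X[out], y[out]).predict(t)
        ok_part = np.exp(OrdinaryKriging(variogram=VG).fit(X[bulk], np.log(y[bulk])).predict(t))
        assert np.abs(pred - np.maximum(tin_part + ok_part, 0)).max() < 1e-8

    def test_unknown_variant_rejected(self, rng):
        X = rng.uniform(0, 10, (10, 2))
        with pytest.raises(ValueError, match="variant"):
            CombinedTINOK(variant="bogus").fit(X, np.arange(10.0))


# ---------------------------------------------------------------------------
# CV RMSE + method selection
# ---------------------------------------------------------------------------

class TestMethodSelection:
    def test_exact_method_on_constant_field_zero_rmse(self, rng):
        df = _df(rng.uniform(0, 1000, (60, 2)), np.full(60, 5.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert cv_rmse(df, "OK", k_folds=5, seed=0) == pytest.approx(0.0, abs=1e-8)

    def test_constant_predictor_rmse_near_sd(self, rng):
        vals = rng.normal(100, 10, 500)
        df = _df(rng.uniform(0, 5000, (500, 2)), vals)
        rmse = cv_rmse(df, DummyRegressor(strategy="mean"), k_folds=10, seed=0)
        assert abs(rmse - vals.std()) / vals.std() < 0.10

    def test_kriging_beats_constant_mean_on_smooth_field(self, domain):
        wins = 0
        for s in range(20):
            t = SimulationTruth(seed=4000 + s, outlier_fraction=0.0,
                                background_params=BackgroundParams(4.0, 0.8, 800.0))
            df = generate_soil_field(domain, 150, t)
            ok = cv_rmse(df, "OK", k_folds=5, seed=s)
            const = cv_rmse(df, DummyRegressor(strategy="mean"), k_folds=5, seed=s)
            wins += ok < const
        assert wins >= 18

    def test_row_order_invariance(self, soil):
        shuffled = soil.sample(frac=1.0, random_state=5).reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cv_rmse(soil, "TIN", k_folds=4, seed=2)
            b = cv_rmse(shuffled, "TIN", k_folds=4, seed=2)
        assert a == b

    def test_selection_prefers_exact_over_noisy(self, soil):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, table = select_best_method(soil, ["OK", "TIN"], k_folds=4, seed=0)
        assert len(table) == 2
        assert best == table.sort_values("rmse")["method"].iloc[0]

    def test_single_method_selects_itself(self, soil):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, table = select_best_method(soil, ["TIN"], k_folds=4, seed=0)
        assert best == "TIN" and len(table) == 1

    def test_fold_validation(self, soil):
        with pytest.raises(ValueError):
            cv_rmse(soil, "OK", k_folds=1, seed=0)
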