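"""Spatial regression: kNN weights, Moran's I screening, and the maximum-
likelihood spatial-error model (SEM).

Model:  y = X beta + u,  u = lambda W u + e,  e ~ N(0, sigma^2 I),

with W a row-standardized k-nearest-neighbor weights matrix over home
coordinates (k=1 by default: each child's single nearest neighbor). The SEM
is estimated by profiling the concentrated log-likelihood over lambda in
(-1, 1), with the log-determinant of (I - lambda W) evaluated from the
(generally complex) eigenvalues of W; asymptotic standard errors come from
the information matrix. The screening rule fits OLS first and only refits as
SEM when the Moran's I of the OLS residuals is significant at the configured
p-threshold (0.2 by default).

Coefficients on a log outcome are interpreted multiplicatively:
percent change = 100 (exp(beta) - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.stats import norm, pearsonr
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "knn_weights",
    "MoranResult",
    "morans_i",
    "ModelFit",
    "fit_ols",
    "SpatialErrorModel",
    "fit_sem",
    "screen_and_fit",
    "percent_change",
    "ci_percent",
    "correlation_screen",
    "variance_inflation",
]


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Row-standardized k-nearest-neighbor weights over point ids."""

    ids: np.ndarray
    W: sp.csr_matrix
    k: int
    neighbors: np.ndarray  # (n, k) indices

    @property
    def n(self) -> int:
        return self.W.shape[0]


def knn_weights(points, k: int = 1, ids=None, jitter: float = 1e-6, seed: int = 0) -> SpatialWeights:
    """k-nearest-neighbor spatial weights, row-standardized to sum 1.

    Duplicate coordinates are jittered by ~1e-6 m (logged) so neighbors are
    well defined; no self-neighbors. Deterministic given coordinates and k.
    """
    pts = np.asarray(points, dtype=float).copy()
    n = len(pts)
    if not (1 <= k < n):
        raise ValueError(f"need n > k >= 1 (n={n}, k={k})")
    _, inv, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inv] > 1
    if dup.any():
        log.info("knn_weights: %d duplicate coordinates jittered", int(dup.sum()))
        rng = np.random.default_rng(seed)
        pts[dup] += rng.normal(0.0, jitter, (int(dup.sum()), 2))
    tree = cKDTree(pts)
    _, nb = tree.query(pts, k=k + 1)
    nb = np.atleast_2d(nb)[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    W = sp.csr_matrix((np.full(n * k, 1.0 / k), (rows, nb.ravel())), shape=(n, n))
    if ids is None:
        ids = np.arange(n)
    return SpatialWeights(ids=np.asarray(ids), W=W, k=k, neighbors=nb)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p: float


def morans_i(residuals, weights, permutations: int | None = None,
             seed: int = 0) -> MoranResult:
    """Moran's I of a vector over a spatial weights matrix.

    I = (n / S0) (r' W r) / (r' r) with r centered; z and two-sided p from
    the normality approximation. With ``permutations`` set, the p-value is
    instead the two-sided pseudo p from that many random relabelings of the
    vector (the z-score stays the analytic one).
    """
    r = np.asarray(residuals, dtype=float)
    W = getattr(weights, "W", weights)
    W = sp.csr_matrix(W)
    n = len(r)
    if W.shape[0] != n:
        raise ValueError("residual length does not match weights")
    r = r - r.mean()
    denom = r @ r
    if denom == 0:
        raise ValueError("zero-variance residuals")
    s0 = W.sum()
    I = (n / s0) * (r @ (W @ r)) / denom

    # normality-approximation moments
    Wt = W.T.tocsr()
    s1 = 0.5 * ((W + Wt).power(2)).sum()
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    s2 = ((row + col) ** 2).sum()
    e_i = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z = (I - e_i) / np.sqrt(var)
    if permutations:
        rng = np.random.default_rng(seed)
        null = np.empty(permutations)
        for b in range(permutations):
            rp = rng.permutation(r)
            null[b] = (n / s0) * (rp @ (W @ rp)) / denom
        extreme = np.sum(np.abs(null - e_i) >= abs(I - e_i))
        p = (extreme + 1.0) / (permutations + 1.0)
    else:
        p = 2.0 * norm.sf(abs(z))
    return MoranResult(I=float(I), expected=e_i, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """One fitted biomarker-exposure model (OLS or SEM)."""

    method: str                      # "OLS" or "SEM"
    params: pd.Series                # coefficient estimates (incl. const)
    bse: pd.Series                   # standard errors
    pvalues: pd.Series
    r2: float
    n: int
    resid: np.ndarray
    lam: float | None = None         # spatial autoregression coefficient
    lam_se: float | None = None
    llf: float | None = None
    moran: MoranResult | None = None
    flags: dict = field(default_factory=dict)

    def summary_rows(self) -> pd.DataFrame:
        df = pd.DataFrame({"est": self.params, "se": self.bse, "p": self.pvalues})
        df.attrs["r2"] = self.r2
        df.attrs["n"] = self.n
        return df


def _design(X, add_intercept=True):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["const"] + names
    return Xm, names


def _check_rank(Xm, names):
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify offending columns from the QR diagonal
        _, R = np.linalg.qr(Xm)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_ols(y, X, add_intercept: bool = True) -> ModelFit:
    """Ordinary least squares with residuals exposed for Moran screening."""
    y = np.asarray(y, dtype=float)
    Xm, names = _design(X, add_intercept)
    _check_rank(Xm, names)
    res = sm.OLS(y, Xm).fit()
    return ModelFit(
        method="OLS",
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r2=float(res.rsquared),
        n=len(y),
        resid=np.asarray(res.resid),
        llf=float(res.llf),
    )


class SpatialErrorModel(RegressorMixin, BaseEstimator):
    """Maximum-likelihood spatial-error regression (sklearn-style).

    Parameters
    ----------
    k : int
        Neighbors for the kNN weights built from ``coords`` when no
        ``weights`` is passed to :meth:`fit` (default 1, the single nearest
        neighbor).
    add_intercept : bool
    lam_bounds : tuple
        Search bracket for lambda, strictly inside (-1, 1).

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : trend coefficients.
    lambda_, lambda_se_ : spatial autoregression coefficient and its SE.
    bse_, params_ : standard errors / estimates as Series.
    sigma2_, llf_, r2_ : innovation variance, log-likelihood, pseudo-R^2
        (squared correlation of y with the trend X beta).
    """

    def __init__(self, k: int = 1, add_intercept: bool = True,
                 lam_bounds: tuple = (-0.999, 0.999)):
        self.k = k
        self.add_intercept = add_intercept
        self.lam_bounds = lam_bounds

    def fit(self, X, y, coords=None, weights=None):
        y = np.asarray(y, dtype=float)
        Xm, names = _design(X, self.add_intercept)
        _check_rank(Xm, names)
        n = len(y)
        if weights is None:
            if coords is None:
                raise ValueError("pass coords= or weights= to fit")
            weights = knn_weights(coords, k=self.k)
        W = getattr(weights, "W", weights)
        W = sp.csr_matrix(W)
        Wd = W.toarray()

        if not np.any(Wd):
            # null weights: SEM degenerates to OLS exactly
            ols = fit_ols(y, X, self.add_intercept)
            self._from_ols(ols, names)
            return self

        eig = np.linalg.eigvals(Wd)

        def logdet(lam):
            return np.sum(np.log(np.abs(1.0 - lam * eig)))

        Wy = W @ y
        WX = W @ Xm

        def profile(lam):
            ys = y - lam * Wy
            Xs = Xm - lam * WX
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            e = ys - Xs @ beta
            sigma2 = (e @ e) / n
            ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet(lam)
            return ll, beta, sigma2

        lo, hi = self.lam_bounds
        # coarse grid then Brent refinement: the concentrated likelihood can
        # be multimodal near the boundary for k=1 weights
        grid = np.linspace(lo, hi, 41)
        ll_grid = np.array([profile(l)[0] for l in grid])
        i0 = int(np.argmax(ll_grid))
        a = grid[max(i0 - 1, 0)]
        b = grid[min(i0 + 1, len(grid) - 1)]
        res = minimize_scalar(lambda l: -profile(l)[0], bounds=(a, b), method="bounded",
                              options={"xatol": 1e-8})
        lam = float(res.x)
        ll, beta, sigma2 = profile(lam)
        ll0 = profile(0.0)[0]
        if ll0 > ll:  # optimizer sanity: never worse than the OLS point
            lam, (ll, beta, sigma2) = 0.0, profile(0.0)

        if abs(lam) >= (hi - 1e-6):
            warnings.warn(f"lambda on search boundary ({lam:.4f}); fit flagged")
            boundary = True
        else:
            boundary = False

        # asymptotic SEs from the information matrix (beta block separates)
        B = np.eye(n) - lam * Wd
        Xs = Xm - lam * WX
        XtX = Xs.T @ Xs
        cov_beta = sigma2 * np.linalg.inv(XtX)
        WB = Wd @ np.linalg.inv(B)
        t1 = np.trace(WB @ WB) + np.trace(WB.T @ WB)
        t2 = np.trace(WB)
        info = np.array([[t1, t2 / sigma2], [t2 / sigma2, n / (2 * sigma2**2)]])
        try:
            cov_ls = np.linalg.inv(info)
            lam_se = float(np.sqrt(max(cov_ls[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            lam_se = float("nan")

        trend = Xm @ beta
        r2 = float(np.corrcoef(y, trend)[0, 1] ** 2) if np.std(trend) > 0 else 0.0

        self.feature_names_ = names
        self.params_ = pd.Series(beta, index=names)
        self.bse_ = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
        self.coef_ = beta[1:] if self.add_intercept else beta
        self.intercept_ = beta[0] if self.add_intercept else 0.0
        self.lambda_ = lam
        self.lambda_se_ = lam_se
        self.sigma2_ = float(sigma2)
        self.llf_ = float(ll)
        self.llf_lam0_ = float(ll0)
        self.r2_ = r2
        self.resid_ = y - trend          # u-hat (spatially correlated residual)
        self.boundary_ = boundary
        self.weights_ = weights
        return self

    def _from_ols(self, ols: ModelFit, names):
        self.feature_names_ = names
        self.params_ = ols.params
        self.bse_ = ols.bse
        self.coef_ = ols.params.to_numpy()[1:] if self.add_intercept else ols.params.to_numpy()
        self.intercept_ = ols.params.iloc[0] if self.add_intercept else 0.0
        self.lambda_ = 0.0
        self.lambda_se_ = float("nan")
        self.sigma2_ = float(np.mean(ols.resid**2))
        self.llf_ = ols.llf
        self.llf_lam0_ = ols.llf
        self.r2_ = ols.r2
        self.resid_ = ols.resid
        self.boundary_ = False
        self.weights_ = None

    def predict(self, X):
        Xm, _ = _design(X, self.add_intercept)
        return Xm @ self.params_.to_numpy()

    def to_modelfit(self) -> ModelFit:
        z = self.params_ / self.bse_
        pv = pd.Series(2.0 * norm.sf(np.abs(z)), index=self.params_.index)
        return ModelFit(
            method="SEM",
            params=self.params_,
            bse=self.bse_,
            pvalues=pv,
            r2=self.r2_,
            n=len(self.resid_),
            resid=self.resid_,
            lam=self.lambda_,
            lam_se=self.lambda_se_,
            llf=self.llf_,
            flags={"lambda_on_boundary": self.boundary_},
        )


def fit_sem(y, X, W, add_intercept: bool = True) -> ModelFit:
    """Functional wrapper: ML spatial-error fit against a prebuilt weights matrix."""
    est = SpatialErrorModel(add_intercept=add_intercept).fit(X, y, weights=W)
    return est.to_modelfit()


def screen_and_fit(y, X, points, p_threshold: float = 0.2, k: int = 1,
                   add_intercept: bool = True) -> ModelFit:
    """OLS first; refit as SEM when OLS residuals show Moran autocorrelation.

    The Moran's I of the OLS residuals is always attached to the returned
    fit, whichever branch is taken.
    """
    w = knn_weights(points, k=k)
    ols = fit_ols(y, X, add_intercept)
    mor = morans_i(ols.resid, w)
    if mor.p < p_threshold:
        fit = fit_sem(y, X, w, add_intercept)
    else:
        fit = ols
    fit.moran = mor
    return fit


# ---------------------------------------------------------------------------
# effect interpretation
# ---------------------------------------------------------------------------

_Z = {0.95: 1.96, 0.90: 1.645}


def percent_change(beta: float) -> float:
    """Multiplicative effect of a coefficient on a log outcome, in percent."""
    return 100.0 * np.expm1(beta)


def ci_percent(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Confidence bounds for the percent change: 100 (exp(beta -/+ z se) - 1)."""
    if level not in _Z:
        raise ValueError("level must be 0.90 or 0.95")
    if se <= 0:
        raise ValueError("se must be positive")
    z = _Z[level]
    return (percent_change(beta - z * se), percent_change(beta + z * se))


# ---------------------------------------------------------------------------
# correlation screen + VIF
# ---------------------------------------------------------------------------

def correlation_screen(exposure_table: pd.DataFrame, biomarker_table: pd.DataFrame,
                       min_pairs: int = 10):
    """Log-log Pearson correlations for each (exposure method, biomarker) pair.

    ``exposure_table`` is long (participant_id, method, value); the biomarker
    table is wide with a participant_id column. Nonpositive or missing values
    are dropped pairwise; entries with fewer than ``min_pairs`` complete pairs
    or zero variance are missing. Returns (r matrix, p matrix) as DataFrames
    shaped methods x biomarkers.
    """
    methods = list(exposure_table["method"].unique())
    biomarkers = [c for c in biomarker_table.columns if c != "participant_id"]
    r = pd.DataFrame(index=methods, columns=biomarkers, dtype=float)
    p = pd.DataFrame(index=methods, columns=biomarkers, dtype=float)
    for m in methods:
        sub = exposure_table.loc[exposure_table["method"] == m, ["participant_id", "value"]]
        merged = sub.merge(biomarker_table, on="participant_id")
        for b in biomarkers:
            pair = merged[["value", b]].dropna()
            pair = pair[(pair["value"] > 0) & (pair[b] > 0)]
            if len(pair) < min_pairs:
                continue
            lx, ly = np.log(pair["value"]), np.log(pair[b])
            if lx.std() == 0 or ly.std() == 0:
                continue
            rr, pp = pearsonr(lx, ly)
            r.loc[m, b] = rr
            p.loc[m, b] = pp
    return r, p


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF per column (multicollinearity check; all < 2 on default covariates)."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return pd.Series(
        [variance_inflation_factor(Xm, i + 1) for i in range(X.shape[1])],
        index=list(X.columns),
    )
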