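"""Per-patient comparator models: unregularized MLE VAR and elastic-net
regression with cross-validated penalty selection and bootstrap intervals.

Both baselines fit each patient separately — exactly the practice the
hierarchical model improves on when series are short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .diary_io import DiaryPanel
from .forecast_eval import ForecastResult
from .var_core import build_design, coef_to_matrices, companion_matrix

__all__ = [
    "VarMleFit",
    "EnetFit",
    "fit_var_mle",
    "mle_forecast",
    "mle_forecast_panel",
    "fit_enet_patient",
    "enet_forecast_bootstrap",
    "enet_forecast_panel",
]


@dataclass
class VarMleFit:
    w: np.ndarray        # vec([A_1..A_p])
    Sigma: np.ndarray    # residual covariance, divisor T - p
    p: int
    R: int
    residuals: np.ndarray  # (T-p, R)


def fit_var_mle(series: np.ndarray, p: int = 1) -> VarMleFit:
    """Equation-by-equation least squares VAR(p), no intercept (series are
    centered and detrended).  Raises on (near-)singular designs — short
    series, the regime that motivates regularization."""
    entry = build_design(series, p)
    R = entry.R
    n = entry.n_obs
    if n <= R * p:
        raise ValueError(
            f"underdetermined VAR: T - p = {n} rows for {R * p} regressors"
        )
    X = entry.H.T                    # (n, R*p)
    Yt = entry.Y.T                   # (n, R)
    cond = np.linalg.cond(X.T @ X)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular design: series too short or collinear")
    A_cat_T, *_ = np.linalg.lstsq(X, Yt, rcond=None)   # (R*p, R)
    A_cat = A_cat_T.T                                  # rows: equations
    E = Yt - X @ A_cat_T                               # (n, R)
    Sigma = E.T @ E / n
    return VarMleFit(w=A_cat.reshape(-1, order="F"), Sigma=Sigma, p=p, R=R,
                     residuals=E)


def _recursive_point(A: list[np.ndarray], last_obs: np.ndarray, H: int) -> np.ndarray:
    """Plug-in recursion: (H, R) point forecasts from the last p observations
    (last_obs row 0 = most recent)."""
    p = len(A)
    R = A[0].shape[0]
    lags = last_obs[:p].copy()
    out = np.empty((H, R))
    for h in range(H):
        y = np.zeros(R)
        for i in range(p):
            y += A[i] @ lags[i]
        out[h] = y
        if p > 1:
            lags[1:] = lags[:-1]
        lags[0] = y
    return out


def mle_forecast(fit: VarMleFit, last_obs: np.ndarray, horizon: int = 1,
                 level: float = 0.95) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian plug-in forecast: point + interval from the h-step forecast
    error covariance sum_{j<h} Phi_j Sigma Phi_j^T, where Phi_j are the
    leading blocks of companion-matrix powers.  Parameter uncertainty is
    ignored (plug-in convention; the original interval construction was not
    reported).  ``last_obs`` rows are ordered most-recent-first."""
    A = coef_to_matrices(fit.w, fit.R, fit.p)
    last_obs = np.atleast_2d(np.asarray(last_obs, dtype=float))
    point = _recursive_point(A, last_obs, horizon)
    C = companion_matrix(A)
    R = fit.R
    z = stats.norm.ppf(0.5 + level / 2)
    lo = np.empty_like(point)
    hi = np.empty_like(point)
    cov = np.zeros((R, R))
    Phi = np.eye(C.shape[0])
    for h in range(horizon):
        Phi_h = Phi[:R, :R]      # leading block of C^h
        cov = cov + Phi_h @ fit.Sigma @ Phi_h.T
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        lo[h] = point[h] - z * se
        hi[h] = point[h] + z * se
        Phi = Phi @ C
    return point, lo, hi


def mle_forecast_panel(panel: DiaryPanel, p: int = 1, horizon: int = 1,
                       level: float = 0.95) -> ForecastResult:
    """Fit and forecast every patient of a (preprocessed) training panel."""
    points, los, his, ids = [], [], [], []
    for pt in panel.patients:
        fit = fit_var_mle(pt.values, p)
        last = pt.values[-p:][::-1]
        point, lo, hi = mle_forecast(fit, last, horizon, level)
        points.append(point)
        los.append(lo)
        his.append(hi)
        ids.append(pt.patient_id)
    return ForecastResult(ids, np.stack(points), np.stack(los), np.stack(his),
                          level=level)


@dataclass
class EnetFit:
    """Per-equation elastic-net fits for one patient.

    Objective per equation (sklearn convention, mixing weight 0.5):
        (1/2n) ||y - X b - b0||^2 + penalty * (0.5 ||b||_1 + 0.25 ||b||_2^2).
    """

    coefs: np.ndarray       # (R, R*p) one row of coefficients per equation
    intercepts: np.ndarray  # (R,)
    penalties: np.ndarray   # (R,) chosen by CV + one-SE rule
    p: int
    R: int
    residuals: np.ndarray   # (T-p, R) training residuals


def _enet_path_cv(X: np.ndarray, y: np.ndarray, n_folds: int,
                  rng: np.random.Generator) -> tuple[float, float, np.ndarray]:
    """3-fold CV over a log-spaced penalty path; return the one-SE penalty,
    the refit intercept, and refit coefficients."""
    n = X.shape[0]
    alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * 0.5)
    alpha_max = max(alpha_max, 1e-6)
    alphas = np.geomspace(alpha_max, alpha_max * 1e-3, 50)
    kf = KFold(n_splits=n_folds, shuffle=True,
               random_state=int(rng.integers(0, 2**31 - 1)))
    cv_mse = np.zeros((n_folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(X)):
        for a, alpha in enumerate(alphas):
            model = ElasticNet(alpha=alpha, l1_ratio=0.5, fit_intercept=True,
                               max_iter=5000, tol=1e-6)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            cv_mse[f, a] = np.mean((y[te] - pred) ** 2)
    mean_mse = cv_mse.mean(axis=0)
    se_mse = cv_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_mse))
    threshold = mean_mse[best] + se_mse[best]
    # largest penalty (alphas descend) within one SE of the minimum
    chosen = int(np.flatnonzero(mean_mse <= threshold)[0])
    model = ElasticNet(alpha=alphas[chosen], l1_ratio=0.5, fit_intercept=True,
                       max_iter=10000, tol=1e-8)
    model.fit(X, y)
    return float(alphas[chosen]), float(model.intercept_), model.coef_.copy()


def fit_enet_patient(series: np.ndarray, p: int = 1, n_folds: int = 3,
                     seed: int = 0) -> EnetFit:
    """Per-equation elastic net (equal L1/L2 weights, mixing 0.5) with
    seeded n-fold CV and the one-standard-error penalty rule."""
    entry = build_design(series, p)
    R = entry.R
    n = entry.n_obs
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} rows after lagging, got {n}")
    X = entry.H.T
    Yt = entry.Y.T
    rng = np.random.default_rng(seed)
    coefs = np.zeros((R, R * p))
    intercepts = np.zeros(R)
    penalties = np.zeros(R)
    for r in range(R):
        penalties[r], intercepts[r], coefs[r] = _enet_path_cv(X, Yt[:, r], n_folds, rng)
    residuals = Yt - (X @ coefs.T + intercepts)
    return EnetFit(coefs=coefs, intercepts=intercepts, penalties=penalties,
                   p=p, R=R, residuals=residuals)


def enet_forecast_bootstrap(fit: EnetFit, last_obs: np.ndarray, horizon: int = 1,
                            B: int = 500, level: float = 0.95,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residual-bootstrap predictive intervals around the plug-in forecast.

    Each bootstrap path re-runs the recursion adding a training residual
    (row resampled with replacement) at every step; interval = percentile
    band of the bootstrap paths, point = noise-free plug-in path.
    """
    rng = np.random.default_rng(seed)
    R, p = fit.R, fit.p
    A = [fit.coefs[:, i * R:(i + 1) * R] for i in range(p)]
    last_obs = np.atleast_2d(np.asarray(last_obs, dtype=float))
    lags0 = last_obs[:p]

    def recurse(noise):  # noise: (horizon, R)
        lags = lags0.copy()
        out = np.empty((horizon, R))
        for h in range(horizon):
            y = fit.intercepts.copy()
            for i in range(p):
                y += A[i] @ lags[i]
            y = y + noise[h]
            out[h] = y
            if p > 1:
                lags[1:] = lags[:-1]
            lags[0] = y
        return out

    point = recurse(np.zeros((horizon, R)))
    n_res = fit.residuals.shape[0]
    paths = np.empty((B, horizon, R))
    for b in range(B):
        idx = rng.integers(0, n_res, size=horizon)
        paths[b] = recurse(fit.residuals[idx])
    half = (1 - level) / 2 * 100
    lo = np.percentile(paths, half, axis=0)
    hi = np.percentile(paths, 100 - half, axis=0)
    return point, lo, hi


def enet_forecast_panel(panel: DiaryPanel, p: int = 1, horizon: int = 1,
                        n_folds: int = 3, B: int = 500, level: float = 0.95,
                        seed: int = 0) -> ForecastResult:
    """Fit + bootstrap-forecast every patient of a training panel."""
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(len(panel.patients))
    points, los, his, ids = [], [], [], []
    for pt, ss in zip(panel.patients, seeds):
        child = ss.generate_state(2)
        fit = fit_enet_patient(pt.values, p, n_folds, seed=int(child[0] % 2**31))
        last = pt.values[-p:][::-1]
        point, lo, hi = enet_forecast_bootstrap(
            fit, last, horizon, B, level, seed=int(child[1] % 2**31)
        )
        points.append(point)
        los.append(lo)
        his.append(hi)
        ids.append(pt.patient_id)
    return ForecastResult(ids, np.stack(points), np.stack(los), np.stack(his),
                          level=level)
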