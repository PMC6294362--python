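"""Point estimates, intervals, significance flags, heterogeneity and
convergence diagnostics for posterior draws.

Point estimates are posterior *modes*: the draw value maximizing a Gaussian
kernel density estimate over the draws.  Because shrinkage priors place
posterior mass at (near) zero, the mode is the sparsity-preserving point
estimate, unlike the posterior mean.  Intervals are equal-tailed empirical
quantiles (linear-interpolation rule); a coefficient is flagged significant
at level alpha when its (1 - alpha) interval excludes zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "empirical_mode",
    "credible_interval",
    "significant",
    "heterogeneity_sd",
    "gelman_rubin",
    "chain_autocorrelation",
    "summarize_by_group",
    "coef_table",
]


def empirical_mode(draws: np.ndarray) -> float:
    """Highest-empirical-density point estimate.

    Evaluates a Gaussian KDE (Silverman bandwidth) at the draw values and
    returns the maximizing draw; ties break toward the smallest absolute
    value, favoring sparsity.  Requires at least 50 draws.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 50:
        raise ValueError("empirical_mode needs at least 50 draws")
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    dens = kde(draws)
    best = dens == dens.max()
    candidates = draws[best]
    return float(candidates[np.argmin(np.abs(candidates))])


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed central interval from empirical quantiles (type-7 rule)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    draws = np.asarray(draws, dtype=float).ravel()
    half = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [half, 1.0 - half])
    return float(lo), float(hi)


def significant(draws: np.ndarray, level: float = 0.95) -> bool:
    """True when the central `level` interval excludes zero."""
    lo, hi = credible_interval(draws, level)
    return lo > 0 or hi < 0


def heterogeneity_sd(theta_draws: np.ndarray) -> np.ndarray:
    """Posterior-mode between-patient SDs, one per coefficient.

    theta_draws has shape (n_draws, k) of deviation *precisions*; the SD is
    theta^{-1/2}, transformed before taking the mode since the mode is not
    equivariant under nonlinear transforms.
    """
    theta_draws = np.asarray(theta_draws, dtype=float)
    if np.any(theta_draws <= 0):
        raise ValueError("deviation precisions must be positive")
    sd_draws = theta_draws ** (-0.5)
    return np.array([empirical_mode(sd_draws[:, k]) for k in range(sd_draws.shape[1])])


def gelman_rubin(chains: list[np.ndarray]) -> float | np.ndarray:
    """Potential scale reduction factor R-hat (between/within chain
    variances, classic non-split formulation).

    ``chains`` is a list (>= 2) of equal-length draw arrays; trailing axes
    index parameters, and an R-hat is returned per parameter.
    """
    if len(chains) < 2:
        raise ValueError("gelman_rubin needs at least 2 chains")
    arrs = [np.asarray(c, dtype=float) for c in chains]
    n = arrs[0].shape[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("chains must have identical shapes")
    if n < 10:
        raise ValueError("chains too short for a stable R-hat")
    x = np.stack(arrs)  # (m, n, ...)
    m = x.shape[0]
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W == 0, 1.0, rhat)
    return float(rhat) if rhat.ndim == 0 else rhat


def max_gelman_rubin(draws) -> float:
    """Max R-hat over every identified scalar parameter of a PosteriorDraws
    object.  The expansion factor alpha and the raw deviations/precisions it
    multiplies are non-identified by construction and are excluded; their
    identified combinations (v_star, theta_v = theta_raw / alpha^2) are
    included."""
    worst = 1.0
    for name in ("w", "v_star", "Lambda", "theta_v", "two_tau2"):
        per_chain = [c.reshape(c.shape[0], -1) for c in draws.per_chain(name)]
        worst = max(worst, float(np.nanmax(gelman_rubin(per_chain))))
    return worst


def chain_autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation function at lags 0..max_lag."""
    chain = np.asarray(chain, dtype=float).ravel()
    n = chain.size
    if n <= max_lag:
        raise ValueError("chain length must exceed max_lag")
    x = chain - chain.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return np.concatenate([[1.0], np.zeros(max_lag)])
    return np.array([np.dot(x[: n - h], x[h:]) / denom for h in range(max_lag + 1)])


def coef_table(draws, levels=(0.10, 0.05), coef_names=None) -> pd.DataFrame:
    """Population-coefficient summary: mode, intervals and significance
    flags at each level, one row per coefficient."""
    w = draws.stacked("w")
    k = w.shape[1]
    names = coef_names or [f"w[{i}]" for i in range(k)]
    rows = []
    for i in range(k):
        row = {"coef": names[i], "mode": empirical_mode(w[:, i]),
               "mean": float(w[:, i].mean())}
        for a in levels:
            lo, hi = credible_interval(w[:, i], 1 - a)
            row[f"lo{100 * (1 - a):.0f}"] = lo
            row[f"hi{100 * (1 - a):.0f}"] = hi
            row[f"sig{100 * (1 - a):.0f}"] = lo > 0 or hi < 0
        rows.append(row)
    return pd.DataFrame(rows)


def hier_aic(draws, designs) -> float:
    """AIC of the hierarchical fit: log likelihood evaluated at the
    posterior-mode patient coefficients w_n and entrywise posterior-mode
    innovation precision, with parameter count R^2 p (N+1) + R(R+1)/2 +
    5 R^2 p (see var_core.hier_param_count).  Smaller is better; used to
    choose the VAR order."""
    from .var_core import aic, hier_param_count, var_log_likelihood

    w_n = draws.stacked("w_n")  # (S, N, k)
    coefs = [
        np.array([empirical_mode(w_n[:, n, j]) for j in range(w_n.shape[2])])
        for n in range(w_n.shape[1])
    ]
    Lam_draws = draws.stacked("Lambda")
    Lam = np.array([[empirical_mode(Lam_draws[:, i, j]) for j in range(draws.R)]
                    for i in range(draws.R)])
    Lam = 0.5 * (Lam + Lam.T)
    # entrywise modes need not be PD for ill-mixed runs; fall back to the mean
    if np.any(np.linalg.eigvalsh(Lam) <= 0):
        Lam = Lam_draws.mean(axis=0)
    ll = var_log_likelihood(designs, coefs, Lam)
    return aic(ll, hier_param_count(draws.R, draws.p, draws.N))


def summarize_by_group(patient_modes: np.ndarray, labels, coef_names=None) -> pd.DataFrame:
    """Five-number summaries of per-patient coefficient modes within groups.

    ``patient_modes`` is (N, k) — typically posterior modes of the combined
    coefficients w + v*_n; ``labels`` assigns each patient to a group.
    """
    patient_modes = np.asarray(patient_modes, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != patient_modes.shape[0]:
        raise ValueError("one label per patient required")
    k = patient_modes.shape[1]
    names = coef_names or [f"w[{i}]" for i in range(k)]
    rows = []
    for g in pd.unique(labels):
        sel = patient_modes[labels == g]
        if sel.shape[0] == 0:
            raise ValueError(f"empty group {g!r}")
        for i in range(k):
            q0, q1, q2, q3, q4 = np.quantile(sel[:, i], [0, 0.25, 0.5, 0.75, 1])
            rows.append({"group": g, "coef": names[i], "n": sel.shape[0],
                         "min": q0, "q1": q1, "median": q2, "q3": q3, "max": q4})
    return pd.DataFrame(rows)
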