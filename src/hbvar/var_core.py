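"""Deterministic VAR(p) machinery shared by the sampler and the baselines.

Model: y_t = sum_i A_i y_{t-i} + eps_t, eps_t ~ MVN(0, Lambda^{-1}), with
A_i the R x R lag-i coefficient matrices.  Stacked form: the response
vector y (length (T-p)*R) equals (H^T kron I_R) w + eps, where column t of
the (R*p) x (T-p) regressor matrix H holds the lags (y_{t-1}; ...; y_{t-p})
and w = vec([A_1, ..., A_p]) is the column-major vectorization of the
horizontally concatenated coefficient matrices (length R^2 p).

All modules share the vec convention exclusively through coef_to_matrices /
matrices_to_coef.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DesignEntry",
    "build_design",
    "build_design_set",
    "coef_to_matrices",
    "matrices_to_coef",
    "companion_matrix",
    "companion_spectral_radius",
    "var_log_likelihood",
    "aic",
    "hier_param_count",
]


@dataclass
class DesignEntry:
    """Stacked response/regressor pair for one patient.

    Y is the R x (T-p) matrix of responses (column t is y_{p+t}); H is the
    (R*p) x (T-p) regressor matrix.  The stacked response vector is
    vec(Y) and the stacked design is (H^T kron I_R), so that residuals are
    Y - A_cat @ H with A_cat = [A_1, ..., A_p] (R x R*p).
    """

    patient_id: str
    Y: np.ndarray
    H: np.ndarray
    p: int

    @property
    def R(self) -> int:
        return self.Y.shape[0]

    @property
    def n_obs(self) -> int:
        """Number of response time points, T - p."""
        return self.Y.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Stacked response vector of length (T-p)*R (column-major over Y)."""
        return self.Y.reshape(-1, order="F")


def build_design(series: np.ndarray, p: int, patient_id: str = "") -> DesignEntry:
    """Build the stacked response/regressor pair for one T x R series."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    T, R = series.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if T <= p:
        raise ValueError(f"need T > p, got T={T}, p={p}")
    n = T - p
    Y = series[p:].T  # R x n
    H = np.empty((R * p, n))
    for i in range(1, p + 1):
        # lag-i block: rows (i-1)*R .. i*R, column t holds y_{p+t-i}
        H[(i - 1) * R : i * R, :] = series[p - i : T - i].T
    return DesignEntry(patient_id=patient_id, Y=Y, H=H, p=p)


def build_design_set(panel, p: int) -> list[DesignEntry]:
    """Design entries for every patient of a (preprocessed) DiaryPanel."""
    return [build_design(pt.values, p, pt.patient_id) for pt in panel.patients]


def coef_to_matrices(w: np.ndarray, R: int, p: int) -> list[np.ndarray]:
    """Unpack w = vec([A_1, ..., A_p]) into the p R x R lag matrices."""
    w = np.asarray(w, dtype=float)
    if w.shape != (R * R * p,):
        raise ValueError(f"coefficient vector must have length R^2*p = {R * R * p}")
    A_cat = w.reshape(R, R * p, order="F")
    return [A_cat[:, i * R : (i + 1) * R].copy() for i in range(p)]


def matrices_to_coef(matrices: list[np.ndarray]) -> np.ndarray:
    """Inverse of coef_to_matrices."""
    A_cat = np.hstack([np.asarray(A, dtype=float) for A in matrices])
    return A_cat.reshape(-1, order="F")


def companion_matrix(matrices: list[np.ndarray]) -> np.ndarray:
    """pR x pR companion matrix of a VAR(p)."""
    p = len(matrices)
    R = matrices[0].shape[0]
    C = np.zeros((p * R, p * R))
    C[:R, :] = np.hstack(matrices)
    if p > 1:
        C[R:, :-R] = np.eye((p - 1) * R)
    return C


def companion_spectral_radius(matrices: list[np.ndarray]) -> float:
    """Spectral radius of the companion matrix; < 1 iff the VAR is stable."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(matrices)))))


def _residual_matrix(entry: DesignEntry, w: np.ndarray) -> np.ndarray:
    R, p = entry.R, entry.p
    A_cat = w.reshape(R, R * p, order="F")
    return entry.Y - A_cat @ entry.H


def var_log_likelihood(
    designs: list[DesignEntry],
    coefs: list[np.ndarray] | np.ndarray,
    Lambda: np.ndarray,
) -> float:
    """Gaussian log likelihood of the panel under per-patient coefficients.

    ``coefs`` is one vector per patient (or a single shared vector); Lambda
    is the common R x R innovation precision.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    R = designs[0].R
    if not np.allclose(Lambda, Lambda.T):
        raise ValueError("Lambda must be symmetric")
    sign, logdet = np.linalg.slogdet(Lambda)
    if sign <= 0:
        raise ValueError("Lambda must be positive definite")
    if isinstance(coefs, np.ndarray) and coefs.ndim == 1:
        coefs = [coefs] * len(designs)
    total = 0.0
    for entry, w in zip(designs, coefs, strict=True):
        E = _residual_matrix(entry, np.asarray(w, dtype=float))
        n = entry.n_obs
        quad = float(np.sum(E * (Lambda @ E)))
        total += 0.5 * n * (logdet - R * np.log(2 * np.pi)) - 0.5 * quad
    return total


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, 2k - 2 log L."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return 2.0 * n_params - 2.0 * loglik


def hier_param_count(R: int, p: int, N: int) -> int:
    """Parameter count used for the hierarchical model's AIC.

    Population + patient coefficient vectors: R^2 p (N + 1); the free
    entries of the innovation precision: R(R+1)/2; and the five per-
    coefficient hyperparameter vectors (expansion factor, latent scale,
    both shrinkage weights, deviation precision): 5 R^2 p.
    """
    k = R * R * p
    return k * (N + 1) + R * (R + 1) // 2 + 5 * k
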