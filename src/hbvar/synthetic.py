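"""Synthetic diary panels drawn from the hierarchical VAR generative model.

Every stage of the pipeline is testable without any external data: a sparse
population coefficient vector, Gaussian patient deviations, a shared
innovation precision, optional linear day trends and completely-at-random
missingness.  Default shapes mirror the substance-use diary study this
model was built for: N = 25 patients, R = 3 variables, order 1, series
lengths 10-33 days averaging about 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diary_io import DiaryPanel, PatientSeries
from .var_core import coef_to_matrices, companion_spectral_radius

__all__ = ["SyntheticTruth", "sample_truth", "simulate_panel", "application1_like_panel"]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a simulated panel."""

    w_true: np.ndarray           # (k,) population coefficients
    v_true: np.ndarray           # (N, k) patient deviations
    Lambda_true: np.ndarray      # (R, R) innovation precision
    R: int
    p: int
    hetero_sd: np.ndarray        # (k,) per-coefficient deviation SDs
    trend_slopes: np.ndarray | None = None   # (N, R)
    missing_rate: float = 0.0
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.v_true.shape[0]

    def patient_coefs(self) -> np.ndarray:
        return self.w_true[None, :] + self.v_true


def sample_truth(R: int = 3, p: int = 1, N: int = 25, sparsity: float = 0.6,
                 hetero_sd=0.1, seed: int = 0, coef_range=(0.1, 0.6),
                 Lambda: np.ndarray | None = None,
                 max_attempts: int = 100) -> SyntheticTruth:
    """Draw a stable ground truth.

    Nonzero entries of w_true are Uniform(+-[0.1, 0.6]); the fraction of
    zero entries is ``sparsity``.  Patient deviations are MVN(0, diag(
    hetero_sd^2)); any patient whose companion spectral radius reaches 1 is
    redrawn (up to ``max_attempts``).
    """
    if not 0 <= sparsity <= 1:
        raise ValueError("sparsity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = R * R * p
    hetero_sd = np.broadcast_to(np.asarray(hetero_sd, dtype=float), (k,)).copy()

    for _ in range(max_attempts):
        n_zero = int(round(sparsity * k))
        zero_idx = rng.choice(k, size=n_zero, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        w = signs * rng.uniform(coef_range[0], coef_range[1], size=k)
        w[zero_idx] = 0.0
        if companion_spectral_radius(coef_to_matrices(w, R, p)) < 1:
            break
    else:
        raise RuntimeError(
            "could not draw a stable population matrix in "
            f"{max_attempts} attempts; reduce coefficient magnitudes"
        )

    v = np.empty((N, k))
    for n in range(N):
        for _ in range(max_attempts):
            v_n = rng.normal(0.0, hetero_sd)
            if companion_spectral_radius(coef_to_matrices(w + v_n, R, p)) < 1:
                v[n] = v_n
                break
        else:
            raise RuntimeError(
                f"patient {n}: no stable deviation in {max_attempts} attempts; "
                "reduce hetero_sd or coefficient magnitudes"
            )
    Lambda_true = np.eye(R) if Lambda is None else np.asarray(Lambda, dtype=float)
    return SyntheticTruth(w_true=w, v_true=v, Lambda_true=Lambda_true, R=R, p=p,
                          hetero_sd=hetero_sd, seed=seed)


def simulate_panel(truth: SyntheticTruth, T, burn_in: int = 200,
                   seed: int = 0) -> DiaryPanel:
    """Simulate a DiaryPanel by iterating the VAR recursion per patient.

    ``T`` is an int or per-patient sequence of series lengths (> p).  Paths
    start from zero lags, run ``burn_in`` extra steps that are discarded,
    then optionally add linear trends and mark cells missing completely at
    random at ``truth.missing_rate``.
    """
    rng = np.random.default_rng(seed)
    R, p, N = truth.R, truth.p, truth.N
    T = np.broadcast_to(np.asarray(T, dtype=int), (N,))
    if np.any(T <= p):
        raise ValueError("every T_n must exceed the order p")
    cov = np.linalg.inv(truth.Lambda_true)
    L = np.linalg.cholesky(cov)
    patients = []
    coefs = truth.patient_coefs()
    for n in range(N):
        A = coef_to_matrices(coefs[n], R, p)
        total = int(T[n]) + burn_in
        y = np.zeros((total + p, R))
        eps = rng.standard_normal((total + p, R)) @ L.T
        for t in range(p, total + p):
            acc = eps[t].copy()
            for i in range(1, p + 1):
                acc += A[i - 1] @ y[t - i]
            y[t] = acc
        series = y[p + burn_in:]
        if truth.trend_slopes is not None:
            days_f = np.arange(1, T[n] + 1, dtype=float)[:, None]
            series = series + days_f * truth.trend_slopes[n][None, :]
        mask = np.zeros_like(series, dtype=bool)
        if truth.missing_rate > 0:
            mask = rng.uniform(size=series.shape) < truth.missing_rate
            # never lose a whole series
            for r in range(R):
                if mask[:, r].all():
                    mask[0, r] = False
        vals = np.where(mask, np.nan, series)
        patients.append(PatientSeries(
            patient_id=f"p{n + 1:02d}",
            days=np.arange(1, T[n] + 1),
            values=vals,
            missing_mask=mask,
        ))
    return DiaryPanel(patients=patients,
                      variable_names=[f"var{r + 1}" for r in range(R)],
                      provenance=["simulated"])


def application1_like_panel(seed: int = 0, N: int = 25, include_meta: bool = True,
                            sparsity: float = 0.6, hetero_sd: float = 0.15,
                            missing_rate: float = 0.02):
    """SYNTHETIC stand-in panel with the shapes of the substance-use diary
    study: N patients, 3 variables (tobacco, negative affect, craving),
    order-1 dynamics, series lengths 10-33 days, a couple of missing days
    per patient, and gender/age demographics for the 8/8/9 group analysis.

    This is simulated data from the generative model — it shares the study's
    dimensions, not its measurements — and is used wherever the real diary
    CSVs (not redistributable here) would be.  Returns (panel, truth).
    """
    rng = np.random.default_rng(seed)
    truth = sample_truth(R=3, p=1, N=N, sparsity=sparsity, hetero_sd=hetero_sd,
                         seed=int(rng.integers(2**31)))
    truth.missing_rate = missing_rate
    lengths = rng.integers(10, 34, size=N)
    # keep the average near the study's ~25.6 days
    lengths = np.clip(lengths + (26 - int(lengths.mean())), 10, 33)
    panel = simulate_panel(truth, lengths, burn_in=200,
                           seed=int(rng.integers(2**31)))
    panel.variable_names = ["tobacco", "negative_affect", "craving"]
    if include_meta:
        genders = []
        ages = []
        for n in range(N):
            grp = n % 3
            if grp == 0:
                genders.append("F"); ages.append(int(rng.integers(18, 22)))
            elif grp == 1:
                genders.append("M"); ages.append(int(rng.integers(18, 22)))
            else:
                genders.append("M"); ages.append(int(rng.integers(22, 33)))
        panel.meta = pd.DataFrame(
            {"gender": genders, "age": ages},
            index=[pt.patient_id for pt in panel.patients],
        )
    return panel, truth
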