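"""Posterior-predictive forecasting and forecast evaluation.

Each posterior draw supplies patient coefficients A_n (from w + v*_n) and an
innovation precision Lambda; a predictive path iterates the VAR recursion
h = 1..H, drawing fresh MVN(0, Lambda^{-1}) noise at every step and feeding
forecasts back in as lags.  Point forecasts are predictive means (the MSE-
optimal summary); intervals are the 2.5th/97.5th predictive percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diary_io import DiaryPanel, PatientSeries
from .var_core import coef_to_matrices

__all__ = [
    "ForecastResult",
    "EvalReport",
    "split_holdout",
    "posterior_forecast",
    "evaluate",
]


@dataclass
class ForecastResult:
    """Forecasts indexed as [patient, horizon, variable].

    point: (N, H, R) predictive means (or plug-in points for baselines);
    lo/hi: (N, H, R) central 95% interval endpoints;
    draws: optional (n_draws, N, H, R) retained predictive draws.
    """

    patient_ids: list[str]
    point: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float = 0.95
    draws: np.ndarray | None = None

    @property
    def H(self) -> int:
        return self.point.shape[1]

    def widths(self) -> np.ndarray:
        return self.hi - self.lo


@dataclass
class EvalReport:
    mse_overall: float
    mse_by_variable: np.ndarray
    coverage: float
    width_narrower_fraction: float | None = None

    def as_dict(self, variable_names=None) -> dict:
        out = {"mse_overall": self.mse_overall, "coverage": self.coverage}
        names = variable_names or [f"var{r}" for r in range(len(self.mse_by_variable))]
        for name, v in zip(names, self.mse_by_variable):
            out[f"mse_{name}"] = float(v)
        if self.width_narrower_fraction is not None:
            out["width_narrower_fraction"] = self.width_narrower_fraction
        return out


def split_holdout(panel: DiaryPanel, n_test: int = 1) -> tuple[DiaryPanel, DiaryPanel]:
    """Split each patient's series by position: last ``n_test`` days become
    the test panel (n_test=1 and n_test=10 are the two diary protocols).

    The split is applied after preprocessing, matching the original
    protocol; the resulting mild leakage through the standardization and
    detrending constants is documented in the methods note.
    """
    train, test = [], []
    for p in panel.patients:
        if p.T <= n_test:
            raise ValueError(
                f"patient {p.patient_id!r}: T={p.T} too short for n_test={n_test}"
            )
        train.append(PatientSeries(p.patient_id, p.days[:-n_test],
                                   p.values[:-n_test], p.missing_mask[:-n_test]))
        test.append(PatientSeries(p.patient_id, p.days[-n_test:],
                                  p.values[-n_test:], p.missing_mask[-n_test:]))
    mk = lambda pts: DiaryPanel(pts, list(panel.variable_names), panel.meta,
                                list(panel.provenance))
    return mk(train), mk(test)


def posterior_forecast(draws, panel: DiaryPanel, horizon: int = 1,
                       seed: int = 0, keep_draws: bool = False) -> ForecastResult:
    """Posterior-predictive recursive forecasts from stored Gibbs draws.

    ``panel`` must be the (preprocessed) training panel the draws were
    fitted on; for each stored draw and patient, the last p observations
    seed the recursion and each step adds noise drawn with precision equal
    to that draw's Lambda.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    R, p = draws.R, draws.p
    w_n = draws.stacked("w_n")          # (S, N, k)
    Lambdas = draws.stacked("Lambda")   # (S, R, R)
    S = w_n.shape[0]
    N = len(panel.patients)
    if draws.patient_ids != [pt.patient_id for pt in panel.patients]:
        raise ValueError("panel patients do not match the fitted draws")
    # innovation Cholesky factors of Lambda^{-1} per draw
    chols = np.linalg.cholesky(np.linalg.inv(Lambdas))
    out = np.empty((S, N, horizon, R))
    for n, pt in enumerate(panel.patients):
        lags0 = pt.values[-p:][::-1].copy()  # row 0 = most recent
        for s in range(S):
            A = coef_to_matrices(w_n[s, n], R, p)
            L = chols[s]
            lags = lags0.copy()
            for h in range(horizon):
                mean = np.zeros(R)
                for i in range(p):
                    mean += A[i] @ lags[i]
                y = mean + L @ rng.standard_normal(R)
                out[s, n, h] = y
                if p > 1:
                    lags[1:] = lags[:-1]
                lags[0] = y
    point = out.mean(axis=0)
    lo = np.percentile(out, 2.5, axis=0)
    hi = np.percentile(out, 97.5, axis=0)
    return ForecastResult(
        patient_ids=list(draws.patient_ids), point=point, lo=lo, hi=hi,
        draws=out if keep_draws else None,
    )


def _truth_array(test_panel: DiaryPanel, H: int) -> np.ndarray:
    truth = np.stack([pt.values[:H] for pt in test_panel.patients])
    return truth  # (N, H, R)


def evaluate(forecasts: ForecastResult, truth: DiaryPanel,
             comparator: ForecastResult | None = None) -> EvalReport:
    """MSE (per variable and overall), 95% coverage, and the fraction of
    intervals narrower than a comparator's, over all (patient, horizon,
    variable) cells of the held-out panel."""
    ids = [pt.patient_id for pt in truth.patients]
    if ids != forecasts.patient_ids:
        missing = sorted(set(ids) ^ set(forecasts.patient_ids))
        raise ValueError(f"forecast/truth patients misaligned: {missing}")
    H = forecasts.H
    if any(pt.T < H for pt in truth.patients):
        raise ValueError("held-out panel shorter than the forecast horizon")
    y = _truth_array(truth, H)
    err2 = (forecasts.point - y) ** 2            # (N, H, R)
    mse_by_var = err2.mean(axis=(0, 1))
    covered = (y >= forecasts.lo) & (y <= forecasts.hi)
    report = EvalReport(
        mse_overall=float(mse_by_var.mean()),
        mse_by_variable=mse_by_var,
        coverage=float(covered.mean()),
    )
    if comparator is not None:
        if comparator.patient_ids != forecasts.patient_ids or comparator.H != H:
            raise ValueError("comparator forecasts misaligned")
        report.width_narrower_fraction = float(
            (forecasts.widths() < comparator.widths()).mean()
        )
    return report
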