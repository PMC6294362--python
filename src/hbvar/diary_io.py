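"""Reading, validation and preprocessing of multi-patient diary panels.

A *diary panel* is a collection of per-patient daily multivariate series:
patient ``n`` records ``R`` numeric variables (e.g. tobacco use, negative
affect, craving) on days ``1..T_n``, possibly with missing days or cells.

The preprocessing pipeline applied before model fitting is, per patient and
per variable, in order: impute missing cells -> log(x + offset) ->
standardize to sample mean 0 / variance 1 -> remove a linear time trend by
OLS on the day index and keep the residuals.  The order is recorded in a
provenance list on the returned panel so it can be audited or flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PatientSeries",
    "DiaryPanel",
    "PreprocessConfig",
    "read_panel_csv",
    "write_panel_csv",
    "daily_average",
    "impute_series",
    "preprocess",
]


@dataclass
class PatientSeries:
    """One patient's day-indexed multivariate series.

    ``values`` is a ``T_n x R`` float matrix; ``missing_mask`` flags cells
    that were absent in the source data.  ``days`` is a strictly increasing
    1-based integer index (gaps allowed until :func:`preprocess` fills them).
    """

    patient_id: str
    days: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.days.ndim != 1:
            raise ValueError("days must be a 1-D integer index")
        if len(np.unique(self.days)) != len(self.days):
            raise ValueError(f"patient {self.patient_id!r}: duplicate days")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"patient {self.patient_id!r}: days must be strictly increasing")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape[0] != self.days.shape[0]:
            raise ValueError("values row count must match days")
        obs = ~self.missing_mask
        if not np.all(np.isfinite(self.values[obs])):
            raise ValueError(
                f"patient {self.patient_id!r}: non-finite value in an observed cell"
            )

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def R(self) -> int:
        return self.values.shape[1]


@dataclass
class DiaryPanel:
    """A set of patients sharing the same R diary variables."""

    patients: list[PatientSeries]
    variable_names: list[str]
    meta: pd.DataFrame | None = None  # indexed by patient_id: gender, age, ...
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.patients) < 1:
            raise ValueError("panel must contain at least one patient (N >= 1)")
        R = len(self.variable_names)
        if R < 1:
            raise ValueError("panel must have at least one variable (R >= 1)")
        for p in self.patients:
            if p.R != R:
                raise ValueError(
                    f"patient {p.patient_id!r} has {p.R} variables, panel declares {R}"
                )

    @property
    def N(self) -> int:
        return len(self.patients)

    @property
    def R(self) -> int:
        return len(self.variable_names)

    def patient(self, patient_id: str) -> PatientSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing switches.

    imputation      'flank_mean' (mean of the nearest observed value on each
                    side of a missing run) or 'moving_average' (centered
                    window mean, window widened at the boundaries).
    ma_window       window size for moving-average imputation (days).
    log_offset      x -> log(x + log_offset); use 1.0 for count-like scales
                    that include 0, 0.0 for strictly positive scales.
    standardize     center/scale each series to sample mean 0, variance 1
                    (denominator T - 1).
    detrend         replace each series by the residuals of OLS on (1, day).
    daily_average   collapse multiple records per (patient, day) to their
                    per-variable mean first.
    """

    imputation: str = "flank_mean"
    ma_window: int = 4
    log_offset: float = 0.0
    log_transform: bool = True
    standardize: bool = True
    detrend: bool = True
    daily_average: bool = False

    def __post_init__(self) -> None:
        if self.imputation not in ("flank_mean", "moving_average"):
            raise ValueError(f"unknown imputation method {self.imputation!r}")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.log_offset < 0:
            raise ValueError("log_offset must be nonnegative")


def read_panel_csv(
    path,
    schema: dict | None = None,
    daily_average_duplicates: bool = False,
) -> DiaryPanel:
    """Read a long-format diary CSV into a :class:`DiaryPanel`.

    Expected columns: a patient id, a day index, and one column per numeric
    diary variable; optional ``gender`` / ``age`` demographic columns.
    ``schema`` may rename non-default columns, e.g.
    ``{"patient_id": "subj", "day": "t", "variables": ["T", "N", "C"]}``.
    Blank cells become missing-mask entries.  Duplicate (patient, day) rows
    raise unless ``daily_average_duplicates`` is set.
    """
    schema = dict(schema or {})
    id_col = schema.get("patient_id", "patient_id")
    day_col = schema.get("day", "day")
    df = pd.read_csv(path, dtype={id_col: str})
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no records (file contains only a header)")
    for col in (id_col, day_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    demo_cols = [c for c in ("gender", "age") if c in df.columns]
    var_cols = schema.get("variables") or [
        c for c in df.columns if c not in (id_col, day_col, *demo_cols)
    ]
    if not var_cols:
        raise ValueError(f"{path}: no numeric variable columns found")

    for c in var_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {c!r} at row {row}")
        df[c] = coerced
    df[day_col] = df[day_col].astype(int)

    dup = df.duplicated(subset=[id_col, day_col], keep=False)
    if dup.any():
        if not daily_average_duplicates:
            keys = (
                df.loc[dup, [id_col, day_col]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise ValueError(
                "duplicate (patient, day) rows: " + ", ".join(map(str, keys))
            )

    patients = []
    meta_rows = {}
    for pid, grp in df.groupby(id_col, sort=True):
        if dup.any():
            grp = grp.groupby(day_col, as_index=False)[var_cols].mean(numeric_only=True)
        grp = grp.sort_values(day_col)
        vals = grp[var_cols].to_numpy(dtype=float)
        mask = ~np.isfinite(vals)
        vals = np.where(mask, np.nan, vals)
        patients.append(
            PatientSeries(
                patient_id=str(pid),
                days=grp[day_col].to_numpy(dtype=int),
                values=vals,
                missing_mask=mask,
            )
        )
        if demo_cols:
            first = df[df[id_col] == pid].iloc[0]
            meta_rows[str(pid)] = {c: first[c] for c in demo_cols}
    meta = pd.DataFrame.from_dict(meta_rows, orient="index") if meta_rows else None
    return DiaryPanel(patients=patients, variable_names=list(var_cols), meta=meta)


def write_panel_csv(panel: DiaryPanel, path) -> None:
    """Write a panel back to the long-format CSV dialect of read_panel_csv."""
    rows = []
    for p in panel.patients:
        for i, day in enumerate(p.days):
            row = {"patient_id": p.patient_id, "day": int(day)}
            for j, name in enumerate(panel.variable_names):
                row[name] = np.nan if p.missing_mask[i, j] else p.values[i, j]
            if panel.meta is not None and p.patient_id in panel.meta.index:
                row.update(panel.meta.loc[p.patient_id].to_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def daily_average(panel: DiaryPanel) -> DiaryPanel:
    """Collapse repeated (patient, day) records to one record per day.

    The value is the mean over that day's *non-missing* entries per variable;
    a day is missing for a variable only if every entry that day is missing.
    Panels read through read_panel_csv are already unique per day; this
    handles panels assembled programmatically from raw multi-entry diaries.
    """
    new_patients = []
    for p in panel.patients:
        uniq_days, inverse = np.unique(p.days, return_inverse=True)
        T, R = len(uniq_days), p.R
        vals = np.zeros((T, R))
        mask = np.zeros((T, R), dtype=bool)
        for t in range(T):
            rows = inverse == t
            sub = p.values[rows]
            obs = ~p.missing_mask[rows]
            for r in range(R):
                if obs[:, r].any():
                    vals[t, r] = sub[obs[:, r], r].mean()
                else:
                    vals[t, r] = np.nan
                    mask[t, r] = True
        new_patients.append(
            PatientSeries(p.patient_id, uniq_days, vals, mask)
        )
    return DiaryPanel(
        patients=new_patients,
        variable_names=list(panel.variable_names),
        meta=panel.meta,
        provenance=panel.provenance + ["daily_average"],
    )


def impute_series(
    values: np.ndarray,
    missing: np.ndarray,
    method: str = "flank_mean",
    window: int = 4,
) -> np.ndarray:
    """Fill missing entries of a single length-T series.

    flank_mean      each missing run is filled with the mean of the nearest
                    observed value before and after the run; a run touching
                    a boundary copies its single observed neighbour.
    moving_average  centered window mean of the observed values, widening
                    the window at the boundaries until it contains at least
                    one observation.
    """
    values = np.asarray(values, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    if values.ndim != 1:
        raise ValueError("impute_series expects a 1-D series")
    if missing.all():
        raise ValueError("cannot impute an all-missing series")
    if not missing.any():
        return values.copy()
    out = values.copy()
    T = len(values)
    obs_idx = np.flatnonzero(~missing)
    if method == "flank_mean":
        for t in np.flatnonzero(missing):
            before = obs_idx[obs_idx < t]
            after = obs_idx[obs_idx > t]
            if len(before) and len(after):
                out[t] = 0.5 * (values[before[-1]] + values[after[0]])
            elif len(before):
                out[t] = values[before[-1]]
            else:
                out[t] = values[after[0]]
    elif method == "moving_average":
        half = max(1, window // 2)
        for t in np.flatnonzero(missing):
            k = half
            while True:
                lo, hi = max(0, t - k), min(T, t + k + 1)
                sel = obs_idx[(obs_idx >= lo) & (obs_idx < hi)]
                if len(sel):
                    out[t] = values[sel].mean()
                    break
                k += 1
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return out


def _fill_day_gaps(p: PatientSeries) -> PatientSeries:
    """Insert missing rows for gaps in the day index (days become consecutive)."""
    full_days = np.arange(p.days[0], p.days[-1] + 1)
    if len(full_days) == len(p.days):
        return p
    T, R = len(full_days), p.R
    vals = np.full((T, R), np.nan)
    mask = np.ones((T, R), dtype=bool)
    pos = p.days - p.days[0]
    vals[pos] = p.values
    mask[pos] = p.missing_mask
    return PatientSeries(p.patient_id, full_days, vals, mask)


def preprocess(panel: DiaryPanel, cfg: PreprocessConfig | None = None) -> DiaryPanel:
    """Run the full preprocessing pipeline on every patient/variable series.

    Order: (daily average) -> fill day gaps -> impute -> log(x + offset) ->
    standardize (mean 0, sample variance 1) -> detrend by OLS on the day
    index.  A constant series cannot be standardized and raises, mirroring
    the exclusion of no-variance diaries from analysis.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.daily_average:
        panel = daily_average(panel)
    steps = ["impute:" + cfg.imputation]
    if cfg.log_transform:
        steps.append(f"log(x+{cfg.log_offset:g})")
    if cfg.standardize:
        steps.append("standardize")
    if cfg.detrend:
        steps.append("detrend")

    new_patients = []
    for p in panel.patients:
        p = _fill_day_gaps(p)
        T = p.T
        out = np.empty_like(p.values)
        for r, name in enumerate(panel.variable_names):
            x = impute_series(
                p.values[:, r], p.missing_mask[:, r], cfg.imputation, cfg.ma_window
            )
            if cfg.log_transform:
                shifted = x + cfg.log_offset
                if np.any(shifted <= 0):
                    raise ValueError(
                        f"patient {p.patient_id!r} variable {name!r}: "
                        f"nonpositive value under log(x+{cfg.log_offset:g}); "
                        "increase log_offset"
                    )
                x = np.log(shifted)
            if cfg.standardize:
                sd = np.std(x, ddof=1) if T > 1 else 0.0
                if sd == 0 or not np.isfinite(sd):
                    raise ValueError(
                        f"patient {p.patient_id!r} variable {name!r}: zero variance, "
                        "cannot standardize (no-variance diaries are excluded)"
                    )
                x = (x - x.mean()) / sd
            if cfg.detrend:
                day = p.days.astype(float)
                X = np.column_stack([np.ones(T), day])
                beta, *_ = np.linalg.lstsq(X, x, rcond=None)
                x = x - X @ beta
            out[:, r] = x
        new_patients.append(
            PatientSeries(p.patient_id, p.days, out, np.zeros_like(p.missing_mask))
        )
    return DiaryPanel(
        patients=new_patients,
        variable_names=list(panel.variable_names),
        meta=panel.meta,
        provenance=panel.provenance + steps,
    )
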