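"""Access to the substance-use diary dataset (when available) and to its
synthetic stand-in.

The diary measurements analysed in the originating study are distributed as
a supplementary zip of CSV files ("S1 Data") alongside its publication; they
are not redistributable with this package.  ``load_application1`` reads
those CSVs once the user has unpacked them locally; tests and scripts fall
back to the clearly-labelled synthetic panel from :mod:`hbvar.synthetic`
otherwise.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd

from .diary_io import DiaryPanel, PatientSeries, impute_series, read_panel_csv

__all__ = [
    "DatasetNotFoundError",
    "load_application1",
    "preprocess_application1",
    "default_data_dir",
]

VARIABLES = ["tobacco", "negative_affect", "craving"]


class DatasetNotFoundError(FileNotFoundError):
    """Raised when the diary CSVs are not present locally."""


def default_data_dir() -> str:
    return os.environ.get(
        "HBVAR_DATA_DIR",
        os.path.join(os.path.dirname(__file__), "..", "..", "data", "application1"),
    )


def load_application1(path: str | None = None) -> DiaryPanel:
    """Load the substance-use diary panel from a local directory.

    ``path`` holds either a single long-format CSV (columns patient_id, day,
    tobacco, negative_affect, craving, optional gender/age) or the per-
    patient CSV files from the supplementary zip, one file per patient with
    a day column and the three variables.  Raises DatasetNotFoundError with
    download instructions when nothing is found.
    """
    path = path or default_data_dir()
    if os.path.isfile(path):
        return read_panel_csv(path)
    single = os.path.join(path, "application1.csv")
    if os.path.isfile(single):
        return read_panel_csv(single)
    csvs = sorted(glob.glob(os.path.join(path, "*.csv"))) if os.path.isdir(path) else []
    if not csvs:
        raise DatasetNotFoundError(
            "substance-use diary data not found under "
            f"{path!r}. Download the originating study's supplementary "
            "'S1 Data' zip, unzip its CSVs into that directory (or set "
            "HBVAR_DATA_DIR), and retry."
        )
    patients = []
    for f in csvs:
        df = pd.read_csv(f)
        cols = {c.lower().strip(): c for c in df.columns}
        day_col = next((cols[c] for c in ("day", "t", "time") if c in cols), None)
        if day_col is None:
            df = df.reset_index().rename(columns={"index": "day"})
            df["day"] = df["day"] + 1
            day_col = "day"
        var_cols = [c for c in df.columns if c != day_col][:3]
        vals = df[var_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
        mask = ~np.isfinite(vals)
        patients.append(PatientSeries(
            patient_id=os.path.splitext(os.path.basename(f))[0],
            days=df[day_col].to_numpy(int),
            values=np.where(mask, np.nan, vals),
            missing_mask=mask,
        ))
    return DiaryPanel(patients=patients, variable_names=VARIABLES[: len(var_cols)])


def preprocess_application1(panel: DiaryPanel) -> DiaryPanel:
    """Study preprocessing for the substance-use diaries: flank-mean
    imputation, log transform (tobacco counts shifted by +1 since 0
    cigarettes is a valid response; the 1-5 affect/craving scales are
    already positive), standardization to mean 0 / variance 1, and removal
    of each series' linear day trend by OLS residuals.
    """
    offsets = {"tobacco": 1.0}
    new_patients = []
    for p in panel.patients:
        T = p.T
        out = np.empty_like(p.values)
        for r, name in enumerate(panel.variable_names):
            x = impute_series(p.values[:, r], p.missing_mask[:, r], "flank_mean")
            x = np.log(x + offsets.get(name, 0.0))
            sd = np.std(x, ddof=1)
            if sd == 0:
                raise ValueError(
                    f"patient {p.patient_id!r} variable {name!r}: no variance"
                )
            x = (x - x.mean()) / sd
            X = np.column_stack([np.ones(T), p.days.astype(float)])
            beta, *_ = np.linalg.lstsq(X, x, rcond=None)
            out[:, r] = x - X @ beta
        new_patients.append(
            PatientSeries(p.patient_id, p.days, out, np.zeros_like(p.missing_mask))
        )
    return DiaryPanel(new_patients, list(panel.variable_names), panel.meta,
                      panel.provenance + ["impute:flank_mean", "log(+1 tobacco)",
                                          "standardize", "detrend"])
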