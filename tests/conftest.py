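import numpy as np
import pytest

from hbvar.diary_io import DiaryPanel, PatientSeries


@pytest.fixture
def small_panel_csv(tmp_path):
    """2 patients x 3 days x 3 variables, one blank craving cell."""
    path = tmp_path / "panel.csv"
    path.write_text(
        "patient_id,day,tobacco,negative_affect,craving,gender,age\n"
        "p1,1,2,1.5,3,F,19\n"
        "p1,2,3,1.0,2,F,19\n"
        "p1,3,1,2.0,,F,19\n"
        "p2,1,0,1.2,1,M,24\n"
        "p2,2,4,1.8,2,M,24\n"
        "p2,3,2,1.1,3,M,24\n"
    )
    return path


def ar1_series(a: float, sigma: float, T: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    y = np.empty(T)
    y[0] = rng.standard_normal() * sigma
    for t in range(1, T):
        y[t] = a * y[t - 1] + sigma * rng.standard_normal()
    return y


@pytest.fixture
def scalar_panel():
    """Single-patient univariate AR(1) panel (R = 1, p = 1, T = 12)."""
    y = ar1_series(0.8, 0.5, 12, seed=42)
    return DiaryPanel(
        [PatientSeries("a", np.arange(1, 13), y[:, None], np.zeros((12, 1), bool))],
        ["x"],
    )
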