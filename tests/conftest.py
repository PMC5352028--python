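import numpy as np
import pandas as pd
import pytest

from growthsem.panel import PanelDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_panel_frame(n_subjects=4, waves=range(7), seed=0):
    """Small valid long-format panel with deterministic contents."""
    from growthsem.panel import REQUIRED_COLS

    rng = np.random.default_rng(seed)
    if n_subjects == 0:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in REQUIRED_COLS})
        df["subject_id"] = df["subject_id"].astype(object)
        return df
    rows = []
    for i in range(n_subjects):
        height = 160.0 + 5 * (i % 4)
        for t in waves:
            weight = 60.0 + 2 * i + 0.5 * t
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "gender": "male" if i % 2 == 0 else "female",
                    "age": 40 + i,
                    "race": "white" if i % 3 else "other",
                    "education": 1 + (i % 4),
                    "income": 1 + ((i + 1) % 4),
                    "smoking": "no" if i % 2 else "yes",
                    "alcohol": float(i),
                    "wave": t,
                    "pa_aerobic": int(rng.integers(0, 8)),
                    "pa_general": int(rng.integers(1, 7)),
                    "pa_strength": int(rng.integers(1, 5)),
                    "hdb_fat": int(rng.integers(1, 6)),
                    "hdb_grains": int(rng.integers(1, 6)),
                    "hdb_protein": int(rng.integers(1, 6)),
                    "height_cm": height,
                    "weight_kg": weight,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_panel():
    return PanelDataset(make_panel_frame())


@pytest.fixture
def linear_lgcm_data():
    """Complete-data panel simulated from a known linear growth model."""
    rng = np.random.default_rng(11)
    n = 1500
    truth = {
        "nu": np.array([23.0, 0.2]),
        "psi": np.array([[9.0, 0.1], [0.1, 0.09]]),
        "theta": 1.0,
    }
    eta = rng.multivariate_normal(truth["nu"], truth["psi"], n)
    t = np.arange(7.0)
    Y = eta[:, [0]] + eta[:, [1]] * t + rng.normal(0, np.sqrt(truth["theta"]), (n, 7))
    df = pd.DataFrame(Y, columns=[f"y{k}" for k in range(7)])
    return df, truth
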