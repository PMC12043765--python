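"""Reading and writing survival tables, time preprocessing, model files.

The on-disk format is a comma-separated UTF-8 table with a header row;
the columns ``time`` and ``status`` are reserved, every other column is
a covariate.  An intercept column is prepended internally and never
written to disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boosting import BoostState, model_from_json, model_to_json
from .distribution import SurvivalDataset

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "dataset_to_frame",
    "preprocess_time",
    "inverse_preprocess_time",
    "save_model",
    "load_model",
]


def dataset_to_frame(data: SurvivalDataset) -> pd.DataFrame:
    out = {"time": data.times, "status": data.status}
    for k, name in enumerate(data.columns):
        out[name] = data.X[:, k + 1]
    return pd.DataFrame(out)


def write_survival_csv(data: SurvivalDataset, path) -> None:
    dataset_to_frame(data).to_csv(path, index=False)


def read_survival_csv(path) -> SurvivalDataset:
    df = pd.read_csv(path)
    for required in ("time", "status"):
        if required not in df.columns:
            raise ValueError(f"missing required column '{required}'")
    covariates = [c for c in df.columns if c not in ("time", "status")]
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            raise ValueError(f"missing value in column '{col}', row {int(bad.idxmax())}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric cells in column '{col}'")
    times = df["time"].to_numpy(dtype=float)
    if np.any(times <= 0):
        row = int(np.nonzero(times <= 0)[0][0])
        raise ValueError(f"nonpositive time in row {row}")
    status = df["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        row = int(np.nonzero(~np.isin(status, (0, 1)))[0][0])
        raise ValueError(f"status outside {{0,1}} in row {row}")
    n = len(df)
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in covariates])
    return SurvivalDataset(times=times, status=status.astype(int), X=X,
                           columns=covariates)


def preprocess_time(times, divide_by: float = 5.0, shift: float = 2.0):
    """Stabilizing transform t -> t/divide_by + shift.

    Responses with a wide range and many values near zero destabilize the
    likelihood; dividing by 5 and shifting by 2 keeps the shape of the
    distribution while moving it away from the origin.  Apply identically
    at fit and predict time.
    """
    if divide_by <= 0:
        raise ValueError("divide_by must be > 0")
    return np.asarray(times, dtype=float) / divide_by + shift


def inverse_preprocess_time(times, divide_by: float = 5.0, shift: float = 2.0):
    if divide_by <= 0:
        raise ValueError("divide_by must be > 0")
    return (np.asarray(times, dtype=float) - shift) * divide_by


def save_model(model: BoostState, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> BoostState:
    with open(path, encoding="utf-8") as fh:
        return model_from_json(fh.read())
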