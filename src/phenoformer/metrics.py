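"""Shared regression metrics: R², RMSE, MAE.

Every model in the package — transformer, transfer variants and the four
baselines — is scored by this one implementation so that reported
differences are model differences only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricSet:
    r2: float | None
    rmse: float
    mae: float
    n: int
    trait: str = ""
    seed: int | None = None

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae,
                "n": self.n, "trait": self.trait, "seed": self.seed}


def metrics(y_true: np.ndarray, y_pred: np.ndarray, trait: str = "",
            seed: int | None = None) -> MetricSet:
    """R² = 1 − SSres/SStot (about the mean of the truth), RMSE, MAE.

    Zero-variance truth leaves R² undefined; it is reported as ``None``
    rather than an arbitrary number.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0.0:
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / sstot
    return MetricSet(r2=r2, rmse=rmse, mae=mae, n=y_true.size, trait=trait,
                     seed=seed)
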