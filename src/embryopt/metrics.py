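"""Goodness-of-fit criteria: R-squared, RMSE, and mean bias error.

MBE is signed as predicted minus observed, so a positive value means the
model over-predicts on average.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np


@dataclass(frozen=True)
class FitReport:
    """Fit quality of one model on one data partition."""

    output_name: str
    partition: str  # "train" or "test"
    r2: float
    rmse: float
    mbe: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(observed, predicted, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape[0]} observed vs {pred.shape[0]} predicted")
    if obs.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {obs.size}")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in input vectors")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    The total sum of squares uses deviations of the *observed* values from
    their mean; a constant observed vector leaves it undefined and is
    rejected.
    """
    obs, pred = _pair(observed, predicted, min_n=2)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed vector is constant")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    obs, pred = _pair(observed, predicted, min_n=1)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mbe(observed, predicted) -> float:
    """Mean bias error, mean(predicted - observed)."""
    obs, pred = _pair(observed, predicted, min_n=1)
    return float(np.mean(pred - obs))


def fit_report(output_name: str, partition: str, observed, predicted) -> FitReport:
    """Bundle the three criteria for one output/partition."""
    obs, pred = _pair(observed, predicted, min_n=2)
    return FitReport(
        output_name=output_name,
        partition=partition,
        r2=r_squared(obs, pred),
        rmse=rmse(obs, pred),
        mbe=mbe(obs, pred),
        n=int(obs.size),
    )
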