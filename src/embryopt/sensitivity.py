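"""Leave-one-feature-out variable importance (VSE / VSR).

VSE for input i is the RMSE of a model retrained from scratch with column i
excluded, evaluated over the entire dataset (train + test rows).  VSR is the
ratio of that error to the full-model error; the higher the ratio, the more
the model depended on the removed input.  "Not available" is interpreted as
column exclusion; mean-substitution (evaluate the full model with the column
frozen at its training mean) is available as an alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from embryopt import anfis
from embryopt.metrics import rmse

#: Tie-break priority when VSR values are equal (most important first).
TIE_BREAK_ORDER = ["d24", "bap", "glu", "fru", "suc", "r", "g", "b"]


@dataclass
class SensitivityReport:
    """Per-input VSE, VSR and importance rank for one output model."""

    output_name: str
    variables: list[str]
    vse_values: list[float]
    vsr_values: list[float]
    ranks: list[int]  # 1 = most important
    rmse_full: float
    flagged_constant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "output_name": self.output_name,
            "rmse_full": self.rmse_full,
            "rows": [
                {"variable": v, "vse": e, "vsr": r, "rank": k}
                for v, e, r, k in zip(self.variables, self.vse_values, self.vsr_values, self.ranks)
            ],
            "flagged_constant": self.flagged_constant,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "output": self.output_name,
                "variable": self.variables,
                "vse": self.vse_values,
                "vsr": self.vsr_values,
                "rank": self.ranks,
            }
        )


def vse(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_all: np.ndarray,
    y_all: np.ndarray,
    variable_index: int,
    train_config: anfis.TrainConfig | None = None,
    mode: str = "exclude",
) -> float:
    """Model error with one input unavailable, over all rows.

    ``exclude`` retrains on the remaining columns with identical
    hyperparameters; ``mean`` keeps the full model but freezes the column at
    its training mean during evaluation.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_all = np.asarray(X_all, dtype=float)
    if not 0 <= variable_index < X_train.shape[1]:
        raise IndexError(f"variable_index {variable_index} out of range")
    if mode == "exclude":
        keep = [j for j in range(X_train.shape[1]) if j != variable_index]
        model, _ = anfis.fit(X_train[:, keep], y_train, train_config)
        pred = model.predict(X_all[:, keep])
    elif mode == "mean":
        model, _ = anfis.fit(X_train, y_train, train_config)
        X_sub = X_all.copy()
        X_sub[:, variable_index] = X_train[:, variable_index].mean()
        pred = model.predict(X_sub)
    else:
        raise ValueError("mode must be 'exclude' or 'mean'")
    return rmse(y_all, pred)


def vsr(vse_i: float, rmse_full: float) -> float:
    """Sensitivity ratio vse_i / rmse_full."""
    if rmse_full <= 0:
        raise ValueError("rmse_full must be > 0 (perfect models are degenerate here)")
    return vse_i / rmse_full


def rank_variables(
    vsr_values, variables: list[str], output_name: str = "y", vse_values=None, rmse_full: float = float("nan")
) -> SensitivityReport:
    """Rank inputs by descending VSR; ties follow the stated priority order."""
    vsr_values = [float(v) for v in vsr_values]
    if not all(np.isfinite(vsr_values)):
        raise ValueError("VSR values must be finite")
    if len(vsr_values) != len(variables):
        raise ValueError("one VSR value per variable required")
    prio = {name: i for i, name in enumerate(TIE_BREAK_ORDER)}
    order = sorted(
        range(len(variables)),
        key=lambda i: (-vsr_values[i], prio.get(variables[i], len(prio)), i),
    )
    ranks = [0] * len(variables)
    for place, i in enumerate(order, start=1):
        ranks[i] = place
    return SensitivityReport(
        output_name=output_name,
        variables=list(variables),
        vse_values=[float(v) for v in vse_values] if vse_values is not None else [float("nan")] * len(variables),
        vsr_values=vsr_values,
        ranks=ranks,
        rmse_full=rmse_full,
    )


def sensitivity_report(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_all: np.ndarray,
    y_all: np.ndarray,
    variables: list[str],
    output_name: str,
    train_config: anfis.TrainConfig | None = None,
    mode: str = "exclude",
) -> SensitivityReport:
    """Full VSE/VSR/rank table for one output model."""
    X_train = np.asarray(X_train, dtype=float)
    model, _ = anfis.fit(X_train, y_train, train_config, input_names=variables, output_name=output_name)
    rmse_full = rmse(y_all, model.predict(np.asarray(X_all, dtype=float)))
    vse_values = []
    flagged = []
    for j, name in enumerate(variables):
        if np.unique(X_train[:, j]).size < 2:
            flagged.append(name)
        vse_values.append(
            vse(X_train, y_train, X_all, y_all, j, train_config, mode=mode)
        )
    vsr_values = [vsr(e, rmse_full) for e in vse_values]
    report = rank_variables(
        vsr_values, variables, output_name=output_name, vse_values=vse_values, rmse_full=rmse_full
    )
    report.flagged_constant = flagged
    return report
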