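"""Bias and precision of parameter estimates across replicate fits.

Relative bias and relative root mean square error against the simulation
truth, plus the conventional accuracy (|RBias| <= 15%) and precision
(RRMSE <= 35%) acceptance thresholds for population PK simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BiasPrecisionEntry",
    "rbias",
    "rrmse",
    "meets_criteria",
    "ACCURACY_LIMIT_PCT",
    "PRECISION_LIMIT_PCT",
    "write_bias_table",
]

ACCURACY_LIMIT_PCT = 15.0
PRECISION_LIMIT_PCT = 35.0


@dataclass(frozen=True)
class BiasPrecisionEntry:
    """One scenario row: (truth order, fit order, n subjects) x parameter."""

    truth_order: int
    fit_order: int
    n_subjects: int
    parameter: str
    rbias_pct: float
    rrmse_pct: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.rrmse_pct < 0:
            raise ValueError("RRMSE cannot be negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _check(estimates, truth: float) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    if truth == 0:
        raise ZeroDivisionError("truth value must be non-zero")
    return est


def rbias(estimates, truth: float) -> float:
    """Relative bias in percent: 100 * mean((est - truth) / truth)."""
    est = _check(estimates, truth)
    return float(100.0 * np.mean((est - truth) / truth))


def rrmse(estimates, truth: float) -> float:
    """Relative RMSE in percent: 100 * sqrt(mean(((est - truth)/truth)^2))."""
    est = _check(estimates, truth)
    return float(100.0 * np.sqrt(np.mean(((est - truth) / truth) ** 2)))


def meets_criteria(entry: BiasPrecisionEntry) -> tuple[bool, bool]:
    """(accuracy_ok, precision_ok): |RBias| <= 15% and RRMSE <= 35%.

    Both limits are inclusive; accuracy is judged on the magnitude of the
    signed RBias.
    """
    return (
        abs(entry.rbias_pct) <= ACCURACY_LIMIT_PCT,
        entry.rrmse_pct <= PRECISION_LIMIT_PCT,
    )


def write_bias_table(entries: list[BiasPrecisionEntry], path: str | Path) -> pd.DataFrame:
    """Write scenario rows as a CSV with one row per (truth, fit, n) and
    CL/Vss metric columns."""
    frame = pd.DataFrame([vars(e) for e in entries])
    wide = frame.pivot_table(
        index=["truth_order", "fit_order", "n_subjects", "n_replicates"],
        columns="parameter",
        values=["rbias_pct", "rrmse_pct"],
    )
    wide.columns = [f"{metric}_{param}" for metric, param in wide.columns]
    wide = wide.reset_index()
    wide.to_csv(path, index=False)
    return wide
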