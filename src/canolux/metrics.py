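"""Agreement metrics between paired canopy summaries.

R^2 here is the model-efficiency (Nash-Sutcliffe) form
1 - sum((y - yhat)^2) / sum((y - ybar)^2), NOT the squared Pearson
correlation: it can be negative when the estimates are worse than the
reference mean, which routinely happens when virtual canopies are compared
against realistic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PairedSeries:
    """Reference values ``y`` (realistic canopy) vs estimates ``y_hat``
    (virtual canopy), with optional grouping keys."""

    y: np.ndarray
    y_hat: np.ndarray
    keys: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.y_hat = np.asarray(self.y_hat, dtype=np.float64).ravel()
        if len(self.y) != len(self.y_hat):
            raise ValueError("y and y_hat must have equal length")

    @property
    def n(self) -> int:
        return len(self.y)


def _series(y, y_hat=None) -> PairedSeries:
    if isinstance(y, PairedSeries):
        return y
    return PairedSeries(y, y_hat)


def r_squared(y, y_hat=None) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (may be negative)."""
    s = _series(y, y_hat)
    if s.n < 2:
        raise ValueError("need at least 2 pairs for R^2")
    ss_tot = float(((s.y - s.y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant reference values")
    ss_res = float(((s.y - s.y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(y, y_hat=None) -> float:
    """Root mean square error, in the units of y."""
    s = _series(y, y_hat)
    if s.n < 1:
        raise ValueError("need at least 1 pair for RMSE")
    return float(np.sqrt(((s.y - s.y_hat) ** 2).mean()))


def rrmse(y, y_hat=None) -> float:
    """Relative RMSE: 100 * RMSE / mean(y), in percent."""
    s = _series(y, y_hat)
    ybar = float(s.y.mean())
    if ybar == 0:
        raise ValueError("rRMSE undefined for zero-mean reference values")
    return 100.0 * rmse(s) / ybar
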