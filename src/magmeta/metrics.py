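"""Regression evaluation metrics: MAE, MAPE, and tolerance accuracy.

MAE = (1/n) Σ |ŷ_i − y_i| and MAPE = (100%/n) Σ |(ŷ_i − y_i)/y_i|; both are
zero exactly when predictions match targets.  The average accuracy A is the
fraction of predictions whose relative error is within a tolerance tau — a
counting rule that turns a regression fit into an accuracy in [0, 1], used
for the support-set-capacity sweeps.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mae", "mape", "accuracy_within_tolerance"]


def _check(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: y_true {yt.shape} vs y_pred {yp.shape}")
    if yt.size == 0:
        raise ValueError("metrics of empty vectors are undefined")
    return yt, yp


def mae(y_true, y_pred) -> float:
    """Mean absolute error, in the units of y."""
    yt, yp = _check(y_true, y_pred)
    return float(np.mean(np.abs(yp - yt)))


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, in percent.

    Undefined when any true value is zero; the four measured properties are
    strictly positive, so valid data never triggers this.
    """
    yt, yp = _check(y_true, y_pred)
    if np.any(yt == 0):
        raise ZeroDivisionError("MAPE is undefined for zero true values")
    return float(100.0 * np.mean(np.abs((yp - yt) / yt)))


def accuracy_within_tolerance(y_true, y_pred, tau: float) -> float:
    """Fraction of predictions with relative error <= tau (in [0, 1])."""
    yt, yp = _check(y_true, y_pred)
    if tau <= 0:
        raise ValueError("tolerance tau must be positive")
    if np.any(yt == 0):
        raise ZeroDivisionError("relative error is undefined for zero true values")
    return float(np.mean(np.abs((yp - yt) / yt) <= tau))
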