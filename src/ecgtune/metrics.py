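"""Regression metrics used to score reconstructed ECG signals.

The tuner ranks candidate networks by the coefficient of determination
(R^2) and reports mean absolute error (MAE), mean squared error (MSE) and
the sample standard deviation (SD) of the predicted trace.  All four are
defined on a pair of equal-length vectors: the observed signal ``y`` and
the prediction ``y_hat``.  A channel-by-channel Pearson correlation table
characterizes how much shared information a recording set carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionPair",
    "MetricReport",
    "r_squared",
    "mae",
    "mse",
    "sd",
    "metric_report",
    "correlation_matrix",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input (e.g. constant y)."""


@dataclass(frozen=True)
class PredictionPair:
    """Observed/predicted value pair for one evaluation.

    Parameters
    ----------
    observed : array-like, shape (N,)
        Ground-truth signal values.
    predicted : array-like, shape (N,)
        Model output aligned sample-by-sample with ``observed``.
    """

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float).ravel()
        pred = np.asarray(self.predicted, dtype=float).ravel()
        if obs.shape != pred.shape:
            raise ValueError(
                f"observed and predicted lengths differ: {obs.size} vs {pred.size}"
            )
        if obs.size == 0:
            raise ValueError("empty prediction pair")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)

    @property
    def n(self) -> int:
        return self.observed.size


@dataclass(frozen=True)
class MetricReport:
    """Bundle of the four evaluation metrics for one trained model."""

    r2: float
    mae: float
    mse: float
    sd: float

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "mae": self.mae, "mse": self.mse, "sd": self.sd}


def _as_pair(p) -> PredictionPair:
    if isinstance(p, PredictionPair):
        return p
    y, yhat = p
    return PredictionPair(y, yhat)


def r_squared(p: PredictionPair) -> float:
    """Coefficient of determination, 1 - SSE/SST.

    Negative values are possible (and returned) for predictors worse than
    the observed mean.  Raises :class:`UndefinedMetricError` when the
    observed signal is constant (SST = 0).
    """
    p = _as_pair(p)
    y, yhat = p.observed, p.predicted
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("R^2 undefined: observed signal is constant")
    sse = float(np.sum((y - yhat) ** 2))
    return (sst - sse) / sst


def mae(p: PredictionPair) -> float:
    """Mean absolute error, (1/N) * sum |y_hat - y|."""
    p = _as_pair(p)
    return float(np.mean(np.abs(p.predicted - p.observed)))


def mse(p: PredictionPair) -> float:
    """Mean squared error, (1/N) * sum (y - y_hat)^2."""
    p = _as_pair(p)
    return float(np.mean((p.observed - p.predicted) ** 2))


def sd(values: np.ndarray) -> float:
    """Sample standard deviation with N-1 degrees of freedom."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("sd requires at least 2 values")
    return float(np.std(v, ddof=1))


def metric_report(p: PredictionPair) -> MetricReport:
    """Compute all four metrics; SD is taken over the predicted trace."""
    p = _as_pair(p)
    return MetricReport(
        r2=r_squared(p), mae=mae(p), mse=mse(p), sd=sd(p.predicted)
    )


def correlation_matrix(rec) -> pd.DataFrame:
    """Pearson correlation between every channel pair of a recording set.

    Parameters
    ----------
    rec : RecordingSet or (labels, samples) pair
        Channels-by-samples matrix.  Constant channels yield NaN entries
        (off-diagonal) and trigger a warning; the diagonal is always 1.

    Returns
    -------
    pandas.DataFrame
        Symmetric matrix with channel labels on both axes, entries in
        [-1, 1] as fractions (multiply by 100 for the percent convention).
    """
    if hasattr(rec, "samples"):
        labels, samples = list(rec.labels), np.asarray(rec.samples, dtype=float)
    else:
        labels, samples = rec
        samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("correlation_matrix needs >= 2 equal-length channels")
    stds = samples.std(axis=1)
    constant = stds == 0
    if constant.any():
        bad = [lab for lab, c in zip(labels, constant) if c]
        warnings.warn(f"constant channel(s) {bad}: correlation undefined", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(samples)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)
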