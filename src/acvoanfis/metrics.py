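"""Goodness-of-fit metrics: RMSE, relative error delta%, and small-sample AICc.

delta% is the summed absolute error over the summed observations, times 100
(scale-free under a common positive rescaling of both vectors).  AICc is the
small-sample-corrected Akaike criterion

    AICc = (2 k n + n ln(sigma_eps^2) (n - k - 1)) / (n - k - 1)
         = 2 k n / (n - k - 1) + n ln(sigma_eps^2),

with ``sigma_eps^2`` the maximum-likelihood residual variance SSE / n and
``k`` the number of tuned model parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise MetricError(
            f"length mismatch: observed {obs.shape[0]}, predicted {pred.shape[0]}"
        )
    if obs.size == 0:
        raise MetricError("metrics require at least one sample")
    return obs, pred


def rmse(observed, predicted) -> float:
    """Root-mean-squared error ``sqrt(mean((j - i)^2))``."""
    obs, pred = _paired(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def delta_pct(observed, predicted) -> float:
    """Relative error ``100 * sum|i - j| / sum j``; undefined when the
    observations sum to zero."""
    obs, pred = _paired(observed, predicted)
    denom = obs.sum()
    if denom == 0:
        raise MetricError("delta%% undefined: observations sum to zero")
    return float(100.0 * np.abs(pred - obs).sum() / denom)


def aicc(n: int, k: int, residual_variance: float) -> float:
    """Small-sample AICc from sample count, parameter count and ML residual
    variance.  Requires ``n > k + 1`` and ``residual_variance > 0``."""
    if n <= k + 1:
        raise MetricError(f"AICc requires n > k + 1 (n={n}, k={k})")
    if residual_variance <= 0:
        raise MetricError("AICc requires positive residual variance")
    return (2.0 * k * n + n * math.log(residual_variance) * (n - k - 1)) / (
        n - k - 1
    )


@dataclass(frozen=True)
class MetricsReport:
    """Metrics of one fitted model on one data split.

    ``aicc`` is ``-inf`` for an exact fit (zero residual variance) and
    ``nan`` when ``n <= k + 1`` leaves the correction undefined.
    """

    rmse: float
    delta_pct: float
    aicc: float
    n: int
    k: int
    residual_sd: float


def metrics_report(observed, predicted, k: int) -> MetricsReport:
    """Bundle RMSE, delta% and AICc for an (observed, predicted) pair."""
    obs, pred = _paired(observed, predicted)
    n = obs.size
    sse = float(np.sum((obs - pred) ** 2))
    var = sse / n
    if n <= k + 1:
        a = math.nan
    elif var == 0:
        a = -math.inf
    else:
        a = aicc(n, k, var)
    # delta% is undefined for zero-sum observations (e.g. a constant target
    # normalized to all zeros); the report records nan rather than failing.
    d = delta_pct(obs, pred) if obs.sum() != 0 else math.nan
    return MetricsReport(
        rmse=rmse(obs, pred),
        delta_pct=d,
        aicc=a,
        n=n,
        k=k,
        residual_sd=math.sqrt(var),
    )
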