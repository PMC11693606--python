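"""Weighted block-jackknife estimation.

Standard errors for all derived f-statistics come from a weighted
delete-one-block jackknife over contiguous genomic blocks (blocks carry
unequal weights because chromosome ends rarely align with block size).
The weighted formulas follow Busing, Meijer & van der Leeden (1999), the
same scheme used throughout the f-statistics literature:

    theta_J  = g * theta_hat - sum_j (1 - w_j / W) * theta_(j)
    tau_j    = h_j * theta_hat - (h_j - 1) * theta_(j),   h_j = W / w_j
    var      = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

where ``theta_(j)`` is the statistic recomputed with block ``j`` deleted.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def weighted_mean_statistic(values: np.ndarray, weights: np.ndarray) -> float:
    """Default statistic: block-weighted mean of per-block values."""
    return float(np.average(values, weights=weights, axis=0))


def block_jackknife(
    values: np.ndarray,
    weights: np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife estimate and standard error.

    Parameters
    ----------
    values
        Per-block values, shape ``(B,)`` or ``(B, k)`` for statistics that
        combine several per-block quantities (e.g. an f4 ratio).
    weights
        Positive block weights (bp spans or site counts), shape ``(B,)``.
        Scaling all weights by a constant leaves the result unchanged.
    statistic
        ``statistic(values, weights) -> float`` evaluated on retained
        blocks; defaults to the weighted mean of a 1-d value vector.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    g = values.shape[0]
    if g < 2:
        raise ValueError("block jackknife requires at least 2 blocks")
    if weights.shape != (g,):
        raise ValueError("weights must be one per block")
    if np.any(weights <= 0):
        raise ValueError("block weights must be positive")
    if statistic is None:
        statistic = weighted_mean_statistic

    theta_hat = statistic(values, weights)
    W = weights.sum()
    keep = np.ones(g, dtype=bool)
    theta_del = np.empty(g)
    for j in range(g):
        keep[j] = False
        theta_del[j] = statistic(values[keep], weights[keep])
        keep[j] = True

    h = W / weights
    theta_J = g * theta_hat - np.sum((1.0 - weights / W) * theta_del)
    tau = h * theta_hat - (h - 1.0) * theta_del
    var = np.sum((tau - theta_J) ** 2 / (h - 1.0)) / g
    return float(theta_J), float(np.sqrt(max(var, 0.0)))


def jackknife_mean_and_cov(
    values: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Jackknife estimate and covariance of a vector of weighted means.

    ``values`` has shape ``(B, k)``; each column's statistic is its
    block-weighted mean.  Returns the bias-corrected estimate (k,) and the
    jackknife covariance matrix (k, k) — the uncertainty of the estimate,
    used as the error model for qpWave/qpAdm fits.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    B, k = values.shape
    if B < 2:
        raise ValueError("need at least 2 blocks")
    W = weights.sum()
    total = weights @ values  # (k,)
    theta_hat = total / W
    # delete-one weighted means, vectorized
    theta_del = (total[None, :] - weights[:, None] * values) / (W - weights)[:, None]
    h = W / weights
    theta_J = B * theta_hat - np.sum((1.0 - weights / W)[:, None] * theta_del, axis=0)
    tau = h[:, None] * theta_hat[None, :] - (h - 1.0)[:, None] * theta_del
    dev = tau - theta_J[None, :]
    cov = (dev / (h - 1.0)[:, None]).T @ dev / B
    return theta_J, cov
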