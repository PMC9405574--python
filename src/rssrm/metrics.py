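"""Evaluation metrics: RMSE, van Rossum distance, precision/recall/F1.

The van Rossum distance is computed in its closed pairwise form

    VRD = sum_ij exp(-|u_i - u_j|/tau) + sum_ij exp(-|v_i - v_j|/tau)
          - 2 sum_ij exp(-|u_i - v_j|/tau)

over the true (u) and predicted (v) spike times, which equals (2/tau) times
the integrated squared difference of the trains filtered with the causal
exponential kernel exp(-t/tau).  Times and tau share the millisecond unit;
tau defaults to 1 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "rmse", "van_rossum", "precision_recall_f1"]


@dataclass
class MetricReport:
    """Spike-train agreement counts and scores on a shared grid."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def rmse(u, u_hat) -> float:
    """Root mean squared deviation between true and predicted potentials."""
    u = np.asarray(u, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float)
    if u.shape != u_hat.shape:
        raise ValueError("potential traces must have equal length")
    return float(np.sqrt(np.mean((u - u_hat) ** 2)))


def van_rossum(true_times, pred_times, tau: float = 1.0) -> float:
    """Closed-form van Rossum distance between two spike-time sets."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    u = np.asarray(true_times, dtype=float)
    v = np.asarray(pred_times, dtype=float)

    def cross(x, y):
        if len(x) == 0 or len(y) == 0:
            return 0.0
        return float(np.exp(-np.abs(x[:, None] - y[None, :]) / tau).sum())

    return cross(u, u) + cross(v, v) - 2.0 * cross(u, v)


def precision_recall_f1(true_indicator, pred_indicator) -> MetricReport:
    """Sample-wise precision, recall and F1 of two indicator trains.

    Conventions: identical trains (including two empty ones) score 1 on all
    three; otherwise an undefined ratio (no predicted or no true spikes)
    scores 0.
    """
    t = np.asarray(true_indicator).astype(bool)
    p = np.asarray(pred_indicator).astype(bool)
    if t.shape != p.shape:
        raise ValueError("trains must share the sample grid")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))

    if fp == 0 and fn == 0:
        if tp == 0:
            warnings.warn(
                "both trains are empty; scoring the degenerate pair as 1",
                RuntimeWarning,
                stacklevel=2,
            )
        return MetricReport(tp, fp, fn, 1.0, 1.0, 1.0)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return MetricReport(tp, fp, fn, precision, recall, f1)
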