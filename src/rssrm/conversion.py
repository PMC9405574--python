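"""Converting predicted membrane potentials into spike trains.

Three steps turn a continuous predicted potential into a spike train that can
be compared with the ground truth:

1. quantile/local-maximum detection: with true firing proportion r and an
   inflation coefficient beta, the threshold q is the empirical (1 - r*beta)
   quantile of the predicted potential; a sample spikes iff it exceeds q and
   is a local maximum;
2. maximum-tolerance search: the smallest timing slack tau_max (on the dt
   grid) at which every spike of the smaller of the two trains finds a
   distinct partner within tau_max;
3. tolerance adjustment: each predicted spike matched within the tolerance is
   replaced by its true partner's time, yielding the train that is scored
   with precision/recall/F1.

Matching uses the greedy two-pointer rule over the time-sorted trains (match
when within tau, otherwise advance the earlier side), which attains the
maximum number of matches for points on a line; full-match feasibility is
therefore monotone in tau and tau_max can be located by bisection on the dt
grid, equivalent to sweeping tau upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .izhikevich import SpikeTrain

__all__ = [
    "ConversionConfig",
    "ToleranceResult",
    "potentials_to_spikes",
    "greedy_match",
    "max_tolerance",
    "tolerant_spike_train",
    "select_beta",
    "BETA_GRID_NARROW",
    "BETA_GRID_WIDE",
]

#: 11 uniform candidates on [1, 1.5] — full (unpruned) models
BETA_GRID_NARROW = tuple(np.linspace(1.0, 1.5, 11))
#: 60 log-spaced candidates on [1, 270] — pruned models with oscillatory output
BETA_GRID_WIDE = tuple(np.logspace(0.0, np.log10(270.0), 60))


@dataclass(frozen=True)
class ConversionConfig:
    """Detection and matching settings for one model family."""

    beta_grid: tuple = BETA_GRID_NARROW
    tolerance_cap: float | None = None  # ms; None = uncapped

    def __post_init__(self):
        if len(self.beta_grid) == 0:
            raise ValueError("beta grid must be nonempty")
        if any(b < 1.0 for b in self.beta_grid):
            raise ValueError("inflation coefficients must be >= 1")


@dataclass
class ToleranceResult:
    """Maximum tolerance and the matching that realizes it."""

    tau_max: float
    tau_upper_bound: float
    matching: list  # (true_time, pred_time) pairs
    unmatched_true: np.ndarray
    unmatched_pred: np.ndarray
    capped: bool = False


def potentials_to_spikes(u_hat, r: float, beta: float, dt: float, t0: float = 0.0) -> SpikeTrain:
    """Quantile/local-maximum spike detection on a predicted potential.

    The threshold is the empirical (1 - r*beta) quantile (linear
    interpolation); a sample spikes iff it is above the threshold, strictly
    above its left neighbour and not below its right neighbour.  Endpoints
    never spike.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    rb = r * beta
    if not 0.0 < rb < 1.0:
        raise ValueError(f"estimated firing ratio r*beta={rb} must lie in (0, 1)")
    q = np.quantile(u_hat, 1.0 - rb)
    mid = u_hat[1:-1]
    is_spike = (mid > q) & (mid > u_hat[:-2]) & (mid >= u_hat[2:])
    indicator = np.zeros(len(u_hat), dtype=np.int8)
    indicator[1:-1][is_spike] = 1
    return SpikeTrain.from_indicator(indicator, dt=dt, t0=t0)


def greedy_match(true_times, pred_times, tau: float):
    """Greedy in-order matching of two sorted spike-time sets within tau.

    Returns index pairs (i_true, j_pred).  For points on a line this greedy
    rule yields a maximum-cardinality matching.
    """
    a = np.asarray(true_times, dtype=float)
    b = np.asarray(pred_times, dtype=float)
    pairs = []
    i = j = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tau:
            pairs.append((i, j))
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return pairs


def max_tolerance(true_times, pred_times, dt: float, cap: float | None = None) -> ToleranceResult:
    """Smallest tolerance (multiple of dt) fully matching the smaller train.

    The search upper bound is ``max(|max(pred) - min(true)|,
    |max(true) - min(pred)|)``, at which a complete matching always exists.
    With ``cap`` set, a tolerance above the cap is clipped to it and flagged.
    """
    a = np.sort(np.asarray(true_times, dtype=float))
    b = np.sort(np.asarray(pred_times, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("maximum tolerance is undefined for empty spike sets")
    need = min(len(a), len(b))
    tau_ub = max(abs(b[-1] - a[0]), abs(a[-1] - b[0]))
    k_hi = int(np.ceil(tau_ub / dt + 1e-9))

    def full(k):
        return len(greedy_match(a, b, k * dt)) >= need

    k_lo = 0
    if not full(0):
        # bisection over the dt grid; feasibility is monotone in tau
        lo, hi = 0, k_hi
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if full(mid):
                hi = mid
            else:
                lo = mid
        k_lo = hi
    tau = k_lo * dt

    capped = cap is not None and tau > cap
    if capped:
        tau = float(cap)
    pairs = greedy_match(a, b, tau)
    mi = {i for i, _ in pairs}
    mj = {j for _, j in pairs}
    return ToleranceResult(
        tau_max=float(tau),
        tau_upper_bound=float(tau_ub),
        matching=[(a[i], b[j]) for i, j in pairs],
        unmatched_true=a[[i for i in range(len(a)) if i not in mi]],
        unmatched_pred=b[[j for j in range(len(b)) if j not in mj]],
        capped=capped,
    )


def tolerant_spike_train(
    true_times, pred_times, tau: float, n_steps: int, dt: float, t0: float = 0.0
) -> SpikeTrain:
    """Predicted train with matched spikes moved onto their true partners.

    Every predicted spike matched (greedily, at most one per true spike)
    within ``tau`` is replaced by the true spike time; unmatched predictions
    are kept as they are.  The result is re-gridded to an indicator train.
    """
    if tau < 0:
        raise ValueError("tolerance must be nonnegative")
    a = np.sort(np.asarray(true_times, dtype=float))
    b = np.sort(np.asarray(pred_times, dtype=float))
    pairs = greedy_match(a, b, tau)
    out = b.copy()
    for i, j in pairs:
        out[j] = a[i]
    return SpikeTrain.from_times(np.unique(out), n_steps=n_steps, dt=dt, t0=t0)


def select_beta(
    u_hat,
    truth: SpikeTrain,
    config: ConversionConfig,
    dt: float,
    t0: float = 0.0,
):
    """Pick the inflation coefficient maximizing tolerance-adjusted F1.

    Every feasible beta in the grid (r*beta < 1) is evaluated through the
    full detection / tolerance / adjustment pipeline; ties go to the smallest
    beta.  Returns a dict with the chosen beta, the raw (Algorithm-1) train,
    the tolerance result, the adjusted train and its F1 score.
    """
    from .metrics import precision_recall_f1

    u_hat = np.asarray(u_hat, dtype=float)
    r = truth.r
    if not 0.0 < r < 1.0:
        raise ValueError("the true train must contain at least one spike")
    n = len(u_hat)
    if n != len(truth.indicator):
        raise ValueError("prediction and truth must share the sample grid")

    feasible = [b for b in config.beta_grid if r * b < 1.0]
    if not feasible:
        raise ValueError("no feasible beta in the grid (r too large)")

    best = None
    for beta in feasible:
        raw = potentials_to_spikes(u_hat, r, beta, dt=dt, t0=t0)
        if raw.n_spikes == 0:
            tol, adjusted = None, raw
        else:
            tol = max_tolerance(truth.times, raw.times, dt=dt, cap=config.tolerance_cap)
            adjusted = tolerant_spike_train(
                truth.times, raw.times, tol.tau_max, n_steps=n, dt=dt, t0=t0
            )
        report = precision_recall_f1(truth.indicator, adjusted.indicator)
        if best is None or report.f1 > best["f1"]:
            best = {
                "beta": float(beta),
                "raw_train": raw,
                "adjusted_train": adjusted,
                "tolerance": tol,
                "f1": report.f1,
                "report": report,
            }
    return best
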