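"""Penalized least-squares fitting of membrane potentials.

All model families minimize

    E = 1/2 * sum_t (u(t) - u_hat(t))^2  +  l1 * sum_j |w_j|  +  l2 * sum_j w_j^2

with an unpenalized intercept (the resting potential).  Columns are
standardized internally for the optimization — the penalty acts on the
standardized scale — and weights are transformed back afterwards.  The ridge
part (l1 = 0) is solved in closed form; the lasso/elastic-net part is solved
by scikit-learn's cyclic coordinate descent through the objective mapping
``alpha = (l1 + 2*l2) / n`` and ``l1_ratio = l1 / (l1 + 2*l2)``.

``SparsityTunedRegressor`` bisects log(l1) until the number of surviving
(nonzero) coefficients matches a requested target count, the mechanism used
to prune the spectral model to a fixed parameter budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .basis import DesignMatrix

__all__ = [
    "PenaltySpec",
    "FitResult",
    "PenalizedRegressor",
    "SparsityTunedRegressor",
    "fit",
    "predict",
    "tune_l1_for_count",
    "count_nonzero",
]


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty strengths and the magnitude below which a weight counts as zero."""

    l1: float = 0.0
    l2: float = 0.01
    zero_tol: float = 1e-8

    def __post_init__(self):
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalty strengths must be nonnegative")
        if self.zero_tol <= 0:
            raise ValueError("zero_tol must be positive")


@dataclass
class FitResult:
    """Intercept (resting potential), weights and fit diagnostics."""

    intercept: float
    weights: np.ndarray
    column_labels: list
    penalty: PenaltySpec
    nonzero_count: int
    objective_value: float
    converged: bool = True

    def __post_init__(self):
        if len(self.weights) != len(self.column_labels):
            raise ValueError("one weight per design column required")


def _standardize(X):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (X - mean) / std, mean, std


class PenalizedRegressor(RegressorMixin, BaseEstimator):
    """Least squares with an L1 + L2 penalty and unpenalized intercept.

    Parameters
    ----------
    l1, l2 : float
        Lasso and ridge strengths on the standardized columns.
    zero_tol : float
        Weights with absolute value at or below this (after back-transform)
        count as pruned.
    max_iter, tol : int, float
        Coordinate-descent budget and stopping tolerance (l1 > 0 only).
    """

    def __init__(self, l1=0.0, l2=0.01, zero_tol=1e-8, max_iter=10_000, tol=1e-4):
        self.l1 = l1
        self.l2 = l2
        self.zero_tol = zero_tol
        self.max_iter = max_iter
        self.tol = tol

    def _objective(self, Xs, yc, w_std):
        resid = yc - Xs @ w_std
        return float(
            0.5 * resid @ resid
            + self.l1 * np.abs(w_std).sum()
            + self.l2 * w_std @ w_std
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        PenaltySpec(self.l1, self.l2, self.zero_tol)  # validate
        n = X.shape[0]
        Xs, mean, std = _standardize(X)
        y_mean = y.mean()
        yc = y - y_mean

        if self.l1 == 0.0:
            w_std = _ridge_solve(Xs, yc, self.l2)
            self.n_iter_ = 0
            self.converged_ = True
        else:
            alpha = (self.l1 + 2.0 * self.l2) / n
            l1_ratio = self.l1 / (self.l1 + 2.0 * self.l2)
            enet = ElasticNet(
                alpha=alpha,
                l1_ratio=l1_ratio,
                fit_intercept=False,
                max_iter=self.max_iter,
                tol=self.tol,
                selection="cyclic",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                enet.fit(np.asfortranarray(Xs), yc)
            w_std = enet.coef_.copy()
            self.n_iter_ = int(enet.n_iter_)
            self.converged_ = self.n_iter_ < self.max_iter
            if not self.converged_:
                warnings.warn(
                    "coordinate descent stopped at max_iter="
                    f"{self.max_iter} (objective {self._objective(Xs, yc, w_std):.6g})",
                    RuntimeWarning,
                    stacklevel=2,
                )

        self.coef_ = w_std / std
        self.intercept_ = float(y_mean - mean @ self.coef_)
        self.coef_std_ = w_std
        self.objective_value_ = self._objective(Xs, yc, w_std)
        self.nonzero_count_ = int(np.sum(np.abs(self.coef_) > self.zero_tol))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


def _ridge_solve(Xs, yc, l2):
    """Closed-form ridge minimizing 1/2||yc - Xs w||^2 + l2 ||w||^2.

    Uses the dual (kernel) form when there are more columns than rows.
    """
    n, p = Xs.shape
    reg = 2.0 * l2
    if reg == 0.0:
        return np.linalg.lstsq(Xs, yc, rcond=None)[0]
    if p <= n:
        A = Xs.T @ Xs + reg * np.eye(p)
        return scipy.linalg.solve(A, Xs.T @ yc, assume_a="pos")
    K = Xs @ Xs.T + reg * np.eye(n)
    return Xs.T @ scipy.linalg.solve(K, yc, assume_a="pos")


class SparsityTunedRegressor(RegressorMixin, BaseEstimator):
    """Penalized fit whose L1 strength is bisected to hit a parameter budget.

    Bisection runs on log(l1) between an all-zero upper bracket (the largest
    absolute correlation of a standardized column with the centered target)
    and a lower bracket dense enough to reach the budget, stopping when the
    nonzero count is within ``slack`` (relative, at least one parameter) of
    ``target_count`` or the bracket collapses.  The closest achieved fit is
    kept either way; ``target_reached_`` records whether the slack was met.
    """

    def __init__(
        self,
        target_count=10,
        l2=0.01,
        zero_tol=1e-8,
        slack=0.02,
        max_bisect=40,
        max_iter=10_000,
        tol=1e-4,
        refit=True,
    ):
        self.target_count = target_count
        self.l2 = l2
        self.zero_tol = zero_tol
        self.slack = slack
        self.max_bisect = max_bisect
        self.max_iter = max_iter
        self.tol = tol
        self.refit = refit

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        target = int(self.target_count)
        n, p = X.shape
        if not 1 <= target <= p:
            raise ValueError(f"target_count must be in [1, {p}]")
        tol_count = max(1.0, self.slack * target)

        if target == p:
            est = PenalizedRegressor(
                l1=0.0, l2=self.l2, zero_tol=self.zero_tol,
                max_iter=self.max_iter, tol=self.tol,
            ).fit(X, y)
            self._adopt(est.coef_std_, 0.0, X, y, target_reached=True)
            return self

        Xs, mean, std = _standardize(X)
        Xs = np.asfortranarray(Xs)
        yc = y - y.mean()
        l1_max = float(np.max(np.abs(Xs.T @ yc)))
        if l1_max == 0.0:
            l1_max = 1.0

        # one warm-started coordinate-descent solver shared by every probe:
        # walking the path downward keeps the active set small and fast
        enet = ElasticNet(
            alpha=1.0, l1_ratio=0.5, fit_intercept=False,
            max_iter=self.max_iter, tol=self.tol,
            selection="cyclic", warm_start=True,
        )

        def probe(l1):
            enet.alpha = (l1 + 2.0 * self.l2) / n
            enet.l1_ratio = l1 / (l1 + 2.0 * self.l2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                enet.fit(Xs, yc)
            w = enet.coef_
            count = int(np.sum(np.abs(w / std) > self.zero_tol))
            return count, w.copy()

        def gap(count):
            return abs(count - target)

        best = None  # (gap, l1, count, w)

        def consider(l1, count, w):
            nonlocal best
            key = (gap(count), count < target)
            if best is None or key < (gap(best[2]), best[2] < target):
                best = (gap(count), l1, count, w)

        # coarse path down from l1_max until the budget is reached
        lo = None
        hi = l1_max
        l1 = l1_max
        for _ in range(80):
            l1 *= 0.7
            count, w = probe(l1)
            consider(l1, count, w)
            if count >= target:
                lo = l1
                break
            hi = l1
            if l1 < l1_max * 1e-12:
                break

        if lo is None:
            warnings.warn(
                f"target of {target} nonzero weights unreachable; achieved "
                f"{best[2]}",
                RuntimeWarning,
                stacklevel=2,
            )
            self._adopt(best[3], best[1], X, y, target_reached=False)
            return self

        for _ in range(self.max_bisect):
            if gap(best[2]) <= tol_count or hi / lo < 1.01:
                break
            mid = float(np.sqrt(lo * hi))
            count, w = probe(mid)
            consider(mid, count, w)
            if count >= target:
                lo = mid
            else:
                hi = mid

        reached = gap(best[2]) <= tol_count
        if not reached:
            warnings.warn(
                f"bisection stopped at {best[2]} nonzero weights for a "
                f"target of {target}",
                RuntimeWarning,
                stacklevel=2,
            )
        self._adopt(best[3], best[1], X, y, target_reached=reached)
        return self

    def _adopt(self, w_std, l1, X, y, target_reached):
        Xs, mean, std = _standardize(X)
        yc = y - y.mean()
        if self.refit and l1 > 0.0:
            # the L1 fit selects the surviving parameters but shrinks them;
            # re-optimize the pruned model's weights under the ridge term only
            active = np.abs(w_std / std) > self.zero_tol
            if active.any():
                w_std = np.zeros_like(w_std)
                w_std[active] = _ridge_solve(Xs[:, active], yc, self.l2)
        resid = yc - Xs @ w_std
        self.l1_ = float(l1)
        self.coef_ = w_std / std
        self.intercept_ = float(y.mean() - mean @ self.coef_)
        self.nonzero_count_ = int(np.sum(np.abs(self.coef_) > self.zero_tol))
        self.objective_value_ = float(
            0.5 * resid @ resid
            + l1 * np.abs(w_std).sum()
            + self.l2 * w_std @ w_std
        )
        self.target_reached_ = bool(target_reached)
        self.n_features_in_ = len(self.coef_)

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# Functional wrappers over labeled designs
# ---------------------------------------------------------------------------

def fit(design: DesignMatrix, y, penalty: PenaltySpec | None = None, **kwargs) -> FitResult:
    """Fit a labeled design by penalized least squares."""
    penalty = penalty or PenaltySpec()
    est = PenalizedRegressor(
        l1=penalty.l1, l2=penalty.l2, zero_tol=penalty.zero_tol, **kwargs
    ).fit(design.X, np.asarray(y, dtype=float))
    return FitResult(
        intercept=est.intercept_,
        weights=est.coef_,
        column_labels=list(design.column_labels),
        penalty=penalty,
        nonzero_count=est.nonzero_count_,
        objective_value=est.objective_value_,
        converged=est.converged_,
    )


def predict(result: FitResult, design: DesignMatrix) -> np.ndarray:
    """Predicted potentials ``intercept + X @ w`` for a matching design."""
    if list(design.column_labels) != list(result.column_labels):
        raise ValueError("design columns do not match the fitted weights")
    return result.intercept + design.X @ result.weights


def tune_l1_for_count(
    design: DesignMatrix, y, target_count: int, l2=0.01, zero_tol=1e-8, **kwargs
):
    """Bisect the L1 strength to a nonzero-count target; returns (l1, FitResult)."""
    est = SparsityTunedRegressor(
        target_count=target_count, l2=l2, zero_tol=zero_tol, **kwargs
    ).fit(design.X, np.asarray(y, dtype=float))
    result = FitResult(
        intercept=est.intercept_,
        weights=est.coef_,
        column_labels=list(design.column_labels),
        penalty=PenaltySpec(l1=est.l1_, l2=l2, zero_tol=zero_tol),
        nonzero_count=est.nonzero_count_,
        objective_value=est.objective_value_,
        converged=est.target_reached_,
    )
    return est.l1_, result


def count_nonzero(result: FitResult) -> int:
    """Number of weights above the zero tolerance (intercept excluded)."""
    return int(np.sum(np.abs(result.weights) > result.penalty.zero_tol))
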