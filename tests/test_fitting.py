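"""Penalized least squares: closed-form oracles and the sparsity bisection."""

import warnings

import numpy as np
import pytest
import scipy.linalg

from rssrm.basis import DesignMatrix
from rssrm.fitting import (
    FitResult,
    PenaltySpec,
    PenalizedRegressor,
    SparsityTunedRegressor,
    count_nonzero,
    fit,
    predict,
    tune_l1_for_count,
    _standardize,
)


def orthogonal_pm1_design(n=8, p=3):
    """Columns of +-1 entries: mean 0, std 1, mutually orthogonal."""
    H = scipy.linalg.hadamard(n)
    return H[:, 1 : p + 1].astype(float)


class TestPenalizedRegressor:
    def test_unpenalized_single_column_recovers_identity(self, rng):
        y = rng.normal(size=30)
        est = PenalizedRegressor(l1=0.0, l2=0.0).fit(y[:, None], y)
        assert est.coef_[0] == pytest.approx(1.0)
        assert est.intercept_ == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(est.predict(y[:, None]), y)

    def test_huge_l1_saturates_to_intercept_only(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40) + 3.0
        est = PenalizedRegressor(l1=1e9, l2=0.01).fit(X, y)
        assert est.nonzero_count_ == 0
        assert est.intercept_ == pytest.approx(y.mean())
        assert np.allclose(est.predict(X), y.mean())

    @pytest.mark.parametrize("l1,l2", [(1.0, 0.0), (2.5, 0.5)])
    def test_orthogonal_design_matches_soft_threshold_closed_form(
        self, rng, l1, l2
    ):
        X = orthogonal_pm1_design(n=16, p=4)
        y = rng.normal(size=16, scale=2.0)
        est = PenalizedRegressor(l1=l1, l2=l2, tol=1e-10).fit(X, y)
        yc = y - y.mean()
        c = X.T @ X  # = n * I for +-1 columns
        z = X.T @ yc
        expected = np.sign(z) * np.maximum(np.abs(z) - l1, 0.0) / (
            c[0, 0] + 2.0 * l2
        )
        assert np.allclose(est.coef_, expected, atol=1e-6)

    def test_pure_ridge_matches_direct_linear_solve(self, rng):
        X = rng.normal(size=(25, 7))
        y = rng.normal(size=25)
        l2 = 0.3
        est = PenalizedRegressor(l1=0.0, l2=l2).fit(X, y)
        Xs, mean, std = _standardize(X)
        yc = y - y.mean()
        w = np.linalg.solve(Xs.T @ Xs + 2 * l2 * np.eye(7), Xs.T @ yc)
        assert np.allclose(est.coef_, w / std, atol=1e-10)

    def test_dual_and_primal_ridge_agree_when_overcomplete(self, rng):
        X = rng.normal(size=(15, 40))  # p > n exercises the kernel form
        y = rng.normal(size=15)
        est = PenalizedRegressor(l1=0.0, l2=0.2).fit(X, y)
        Xs, mean, std = _standardize(X)
        yc = y - y.mean()
        w = np.linalg.solve(Xs.T @ Xs + 0.4 * np.eye(40), Xs.T @ yc)
        assert np.allclose(est.coef_, w / std, atol=1e-8)

    def test_objective_non_increasing_with_iteration_budget(self, rng):
        X = rng.normal(size=(60, 30))
        y = X @ rng.normal(size=30) + rng.normal(size=60)
        objs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for max_iter in (1, 2, 5, 20, 200):
                est = PenalizedRegressor(
                    l1=5.0, l2=0.01, max_iter=max_iter, tol=1e-14
                ).fit(X, y)
                objs.append(est.objective_value_)
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            PenalizedRegressor(l1=-1.0).fit(np.ones((4, 1)), np.ones(4))


class TestSparsityTuning:
    def test_nonzero_count_non_increasing_in_l1(self, rng):
        X = rng.normal(size=(80, 50))
        y = X[:, :10] @ rng.normal(size=10) + 0.1 * rng.normal(size=80)
        counts = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for l1 in np.logspace(-2, 3, 12):
                est = PenalizedRegressor(l1=l1, l2=0.01).fit(X, y)
                counts.append(est.nonzero_count_)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_target_equal_to_width_returns_the_full_model(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        est = SparsityTunedRegressor(target_count=8, l2=0.01).fit(X, y)
        assert est.l1_ == 0.0
        assert est.nonzero_count_ == 8
        assert est.target_reached_

    def test_budget_of_one_hits_the_saturated_branch(self, rng):
        X = rng.normal(size=(60, 30))
        y = X[:, 0] * 3.0 + 0.05 * rng.normal(size=60)
        est = SparsityTunedRegressor(target_count=1).fit(X, y)
        assert est.nonzero_count_ == 1

    def test_bisection_reaches_a_moderate_target_within_slack(self, rng):
        X = rng.normal(size=(150, 300))
        y = X @ rng.normal(size=300) * 0.1 + rng.normal(size=150)
        est = SparsityTunedRegressor(target_count=30, slack=0.02).fit(X, y)
        assert abs(est.nonzero_count_ - 30) <= 1
        assert est.target_reached_

    def test_grid_sweep_oracle_brackets_the_bisected_l1(self, rng):
        """The returned l1 reproduces its own count when refit from cold."""
        X = rng.normal(size=(60, 40))
        y = X @ rng.normal(size=40) * 0.2 + rng.normal(size=60)
        est = SparsityTunedRegressor(target_count=8, refit=False).fit(X, y)
        cold = PenalizedRegressor(l1=est.l1_, l2=0.01).fit(X, y)
        assert abs(cold.nonzero_count_ - est.nonzero_count_) <= 1

    def test_refit_keeps_the_active_set_but_lowers_the_residual(self, rng):
        X = rng.normal(size=(100, 60))
        y = X[:, :5] @ np.array([3.0, -2.0, 1.5, 2.5, -1.0])
        raw = SparsityTunedRegressor(target_count=5, refit=False).fit(X, y)
        ref = SparsityTunedRegressor(target_count=5, refit=True).fit(X, y)
        assert set(np.flatnonzero(ref.coef_)) == set(np.flatnonzero(raw.coef_))
        raw_rss = np.sum((y - raw.predict(X)) ** 2)
        ref_rss = np.sum((y - ref.predict(X)) ** 2)
        assert ref_rss <= raw_rss + 1e-9


class TestFunctionalSurface:
    def _design(self, rng, n=20, p=3):
        X = rng.normal(size=(n, p))
        return DesignMatrix(
            X=X, column_labels=[f"c{i}" for i in range(p)],
            target_rows=np.arange(n),
        )

    def test_fit_predict_round_trip(self, rng):
        design = self._design(rng)
        y = rng.normal(size=20)
        result = fit(design, y, PenaltySpec(l1=0.0, l2=0.1))
        u = predict(result, design)
        assert np.allclose(
            u, result.intercept + design.X @ result.weights
        )

    def test_predict_on_mismatched_labels_rejected(self, rng):
        design = self._design(rng)
        other = self._design(rng, p=2)
        result = fit(design, rng.normal(size=20))
        with pytest.raises(ValueError):
            predict(result, other)

    def test_predict_matches_hand_dot_product(self):
        design = DesignMatrix(
            X=np.array([[1.0, 2.0], [0.0, 1.0], [3.0, -1.0]]),
            column_labels=["a", "b"],
            target_rows=np.arange(3),
        )
        result = FitResult(
            intercept=1.0, weights=np.array([2.0, -1.0]),
            column_labels=["a", "b"], penalty=PenaltySpec(),
            nonzero_count=2, objective_value=0.0,
        )
        assert np.allclose(predict(result, design), [1.0, 0.0, 8.0])

    def test_count_nonzero_uses_the_zero_tolerance(self):
        result = FitResult(
            intercept=0.0, weights=np.array([0.0, 1e-12, 3.0]),
            column_labels=["a", "b", "c"], penalty=PenaltySpec(zero_tol=1e-8),
            nonzero_count=1, objective_value=0.0,
        )
        assert count_nonzero(result) == 1

    def test_tune_l1_for_count_returns_matching_metadata(self, rng):
        design = self._design(rng, n=60, p=30)
        y = design.X @ rng.normal(size=30) * 0.3 + rng.normal(size=60)
        l1, result = tune_l1_for_count(design, y, target_count=6)
        assert result.penalty.l1 == l1
        assert abs(result.nonzero_count - 6) <= 1
        assert count_nonzero(result) == result.nonzero_count
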