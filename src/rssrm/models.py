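"""The six neuron-model families as one configurable regressor.

Every family regresses the membrane potential u(t) on features of the
injected current and the (teacher-forced, ground-truth) spike history:

=======  ==========================  ==========================  ==========
family   features                    fitting                     parameters
=======  ==========================  ==========================  ==========
srm      current lags 0..J,          ridge (l2 = 0.01)           J + 1 + Q
         spike lags 1..Q
rsrm     as srm                      L1 pruned to target count   target
ssrm     Fourier basis x {I(t),      ridge (l2 = 0.01)           2 (n - 1)
         S(t-1)}
rssrm    as ssrm                     L1 pruned to target count   target
pcr      leading PCA scores of the   ridge (l2 = 0.01)           target
         srm design
rcr      raised-cosine bumps x       ridge (l2 = 0.01)           target
         {I(t), S(t-1)}
=======  ==========================  ==========================  ==========

Fitting and prediction are teacher-forced: the spike-history features always
come from the ground-truth train, and models are evaluated on the fitted
window (no train/test split).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .basis import FourierFeatures, LaggedFeatures, RaisedCosineFeatures
from .fitting import PenalizedRegressor, SparsityTunedRegressor

__all__ = ["NeuronModel", "MODEL_FAMILIES", "REDUCED_FAMILIES"]

MODEL_FAMILIES = ("srm", "ssrm", "rsrm", "rssrm", "pcr", "rcr")
#: families whose parameter count is pruned/clamped to a shared budget
REDUCED_FAMILIES = ("rsrm", "rssrm", "pcr", "rcr")


def _split_channels(X):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must have two columns: injected current and "
                         "ground-truth spike indicator")
    return X[:, 0], X[:, 1]


def _lag_one(S):
    out = np.zeros_like(S)
    out[1:] = S[:-1]
    return out


class NeuronModel(RegressorMixin, BaseEstimator):
    """One model family fitted to a single trace.

    Parameters
    ----------
    family : str
        One of ``srm, ssrm, rsrm, rssrm, pcr, rcr``.
    target_count : int, optional
        Parameter budget; required for the reduced families.
    J, Q : int, optional
        Current/spike lag counts for the lagged families; both default to
        ``n // 8``.
    l2 : float
        Ridge strength shared by every family.
    slack : float
        Relative tolerance of the pruned-count bisection.

    Attributes
    ----------
    coef_, intercept_ : back-transformed weights and resting potential.
    n_params_ : reported parameter count (nonzero weights for pruned
        families, design width otherwise; the intercept is never counted).
    target_rows_ : trace samples the design rows correspond to.
    explained_variance_ : cumulative explained-variance fraction (pcr only).
    """

    def __init__(
        self,
        family: str = "rssrm",
        target_count: int | None = None,
        J: int | None = None,
        Q: int | None = None,
        l2: float = 0.01,
        zero_tol: float = 1e-8,
        log_offset: float = 1.0,
        slack: float = 0.02,
        max_iter: int = 10_000,
        tol: float = 1e-4,
    ):
        self.family = family
        self.target_count = target_count
        self.J = J
        self.Q = Q
        self.l2 = l2
        self.zero_tol = zero_tol
        self.log_offset = log_offset
        self.slack = slack
        self.max_iter = max_iter
        self.tol = tol

    # -- design -------------------------------------------------------------

    def _build_transformer(self, n):
        family = self.family
        if family in ("srm", "rsrm", "pcr"):
            # n // 8 keeps every stimulus event inside the usable window
            # (rows start at max(J, Q)) while staying within the order of
            # magnitude of the printed lagged-model parameter counts
            J = n // 8 if self.J is None else self.J
            Q = n // 8 if self.Q is None else self.Q
            return LaggedFeatures(J=J, Q=Q)
        if family in ("ssrm", "rssrm"):
            return FourierFeatures(n_freq="full", channel_names=["I", "S"])
        if family == "rcr":
            t = self._require_target()
            return RaisedCosineFeatures(
                n_bumps=(t - t // 2, t // 2), log_offset=self.log_offset
            )
        raise ValueError(f"unknown model family {self.family!r}")

    def _require_target(self):
        if self.target_count is None:
            raise ValueError(
                f"family {self.family!r} needs a target parameter count"
            )
        return int(self.target_count)

    def _channels(self, X):
        I, S = _split_channels(X)
        if self.family in ("srm", "rsrm", "pcr"):
            return np.column_stack([I, S])
        return np.column_stack([I, _lag_one(S)])

    def _design(self, X):
        C = self._channels(X)
        Xd = self.transformer_.transform(C)
        if self.family == "pcr":
            Xd = self.pca_.transform(Xd)
        return Xd

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        C = self._channels(X)
        self.transformer_ = self._build_transformer(n).fit(C)
        self.target_rows_ = getattr(
            self.transformer_, "target_rows_", np.arange(n)
        )
        Xd = self.transformer_.transform(C)

        if self.family == "pcr":
            k = self._require_target()
            if not 1 <= k <= min(Xd.shape):
                raise ValueError(
                    f"target_count={k} exceeds the design rank bound "
                    f"{min(Xd.shape)}"
                )
            self.pca_ = PCA(n_components=k, random_state=0).fit(Xd)
            self.explained_variance_ = float(
                np.sum(self.pca_.explained_variance_ratio_)
            )
            Xd = self.pca_.transform(Xd)

        y_rows = y[self.target_rows_]
        if self.family in ("rsrm", "rssrm"):
            reg = SparsityTunedRegressor(
                target_count=self._require_target(),
                l2=self.l2,
                zero_tol=self.zero_tol,
                slack=self.slack,
                max_iter=self.max_iter,
                tol=self.tol,
            )
        else:
            reg = PenalizedRegressor(
                l1=0.0, l2=self.l2, zero_tol=self.zero_tol,
                max_iter=self.max_iter, tol=self.tol,
            )
        self.regressor_ = reg.fit(Xd, y_rows)

        self.coef_ = self.regressor_.coef_
        self.intercept_ = self.regressor_.intercept_
        if self.family in ("rsrm", "rssrm"):
            self.n_params_ = int(self.regressor_.nonzero_count_)
        else:
            self.n_params_ = Xd.shape[1]
        if self.family == "pcr":
            self.feature_names_ = np.asarray(
                [f"pc{j}" for j in range(1, Xd.shape[1] + 1)], dtype=object
            )
        else:
            self.feature_names_ = self.transformer_.get_feature_names_out()
        self.n_samples_ = n
        return self

    def predict(self, X):
        """Predicted potentials on the fitted window (teacher-forced)."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n_samples_:
            raise ValueError(
                "the time-indexed designs only predict on the fitted trace"
            )
        return self.regressor_.predict(self._design(X))
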