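"""Regressor designs for the six neuron-model families.

Four designs share the same two input channels — the injected current I(t)
and the one-sample-lagged spike indicator S(t-1):

* lagged: raw time lags of I and S (classic linearized spike response model);
* Fourier: each channel multiplied elementwise by the orthogonal Fourier
  basis columns (spectral spike response model);
* raised cosine: each channel multiplied by log-stretched half-cosine bumps;
* PCA: leading principal-component scores of the lagged design.

All transformers follow the scikit-learn fit/transform protocol and expose
``get_feature_names_out``.  Feature counts can be computed without
materializing the (potentially huge) design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "DesignMatrix",
    "fourier_basis_matrix",
    "LaggedFeatures",
    "FourierFeatures",
    "RaisedCosineFeatures",
    "lagged_design",
    "fourier_feature_design",
    "raised_cosine_design",
    "pca_design",
]


@dataclass
class DesignMatrix:
    """A labeled regressor matrix whose rows are aligned to trace samples."""

    X: np.ndarray
    column_labels: list
    target_rows: np.ndarray

    def __post_init__(self):
        if self.X.shape[1] != len(self.column_labels):
            raise ValueError("one label per design column required")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError("duplicate column labels")
        if self.X.shape[0] != len(self.target_rows):
            raise ValueError("target_rows must index every design row")

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def _as_channels(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("channel input must be 1- or 2-dimensional")
    return X


# ---------------------------------------------------------------------------
# Fourier basis
# ---------------------------------------------------------------------------

def n_fourier_pairs(n: int) -> int:
    """Number of (cos, sin) pairs below the Nyquist bound for n samples."""
    return (n - 1) // 2 if n % 2 else n // 2 - 1


def fourier_basis_matrix(n: int) -> np.ndarray:
    """The n-by-n orthogonal Fourier basis on the grid t = 1..n.

    Odd n: a constant column plus (n-1)/2 cos/sin pairs.  Even n: a constant
    column, n/2 - 1 pairs and a final alternating-sign column (-1)^t.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    t = np.arange(1, n + 1)
    cols = [np.ones(n)]
    for i in range(1, n_fourier_pairs(n) + 1):
        arg = 2.0 * np.pi * i * t / n
        cols.append(np.cos(arg))
        cols.append(np.sin(arg))
    if n % 2 == 0:
        cols.append((-1.0) ** t)
    return np.column_stack(cols)


class FourierFeatures(TransformerMixin, BaseEstimator):
    """Elementwise products of input channels with Fourier basis columns.

    Parameters
    ----------
    n_freq : int or "full"
        Number of (cos, sin) frequency pairs per channel.  ``"full"`` uses
        every non-constant basis column — n - 1 columns per channel for a
        length-n trace (the alternating column is included for even n).
    channel_names : sequence of str, optional
        Names used in the feature labels; defaults to ``ch0, ch1, ...``.
    """

    def __init__(self, n_freq="full", channel_names=None):
        self.n_freq = n_freq
        self.channel_names = channel_names

    def _resolved_names(self, n_channels):
        if self.channel_names is not None:
            if len(self.channel_names) != n_channels:
                raise ValueError("one name per channel required")
            return list(self.channel_names)
        return [f"ch{i}" for i in range(n_channels)]

    def fit(self, X, y=None):
        X = _as_channels(X)
        n, n_channels = X.shape
        pairs = n_fourier_pairs(n)
        if self.n_freq == "full":
            self.n_pairs_ = pairs
            self.include_alternating_ = n % 2 == 0
        else:
            k = int(self.n_freq)
            if not 1 <= k <= pairs:
                raise ValueError(
                    f"n_freq={k} violates the Nyquist bound ({pairs} pairs "
                    f"for n={n})"
                )
            self.n_pairs_ = k
            self.include_alternating_ = False
        self.n_samples_ = n
        self.n_channels_ = n_channels
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = self._resolved_names(self.n_channels_)
        out = []
        for name in names:
            for i in range(1, self.n_pairs_ + 1):
                out.append(f"{name}:cos{i}")
                out.append(f"{name}:sin{i}")
            if self.include_alternating_:
                out.append(f"{name}:alt")
        return np.asarray(out, dtype=object)

    @property
    def n_output_features_(self) -> int:
        per_channel = 2 * self.n_pairs_ + int(self.include_alternating_)
        return per_channel * self.n_channels_

    def transform(self, X) -> np.ndarray:
        X = _as_channels(X)
        if X.shape != (self.n_samples_, self.n_channels_):
            raise ValueError("transform input must match the fitted shape")
        n = self.n_samples_
        t = np.arange(1, n + 1)
        blocks = []
        for c in range(self.n_channels_):
            x = X[:, c]
            cols = np.empty((n, 2 * self.n_pairs_ + int(self.include_alternating_)))
            for i in range(1, self.n_pairs_ + 1):
                arg = 2.0 * np.pi * i * t / n
                cols[:, 2 * i - 2] = np.cos(arg) * x
                cols[:, 2 * i - 1] = np.sin(arg) * x
            if self.include_alternating_:
                cols[:, -1] = (-1.0) ** t * x
            blocks.append(cols)
        return np.hstack(blocks)


# ---------------------------------------------------------------------------
# Lagged design
# ---------------------------------------------------------------------------

class LaggedFeatures(TransformerMixin, BaseEstimator):
    """Raw time lags of the current and spike channels.

    One column per current lag s = 0..J and per spike-history lag q = 1..Q;
    rows are restricted to samples where every lag exists, recorded in
    ``target_rows_``.
    """

    def __init__(self, J: int = 0, Q: int = 1):
        self.J = J
        self.Q = Q

    def fit(self, X, y=None):
        X = _as_channels(X)
        if X.shape[1] != 2:
            raise ValueError("lagged design expects two channels (I, S)")
        if self.J < 0 or self.Q < 1:
            raise ValueError("need J >= 0 and Q >= 1")
        n = X.shape[0]
        if max(self.J, self.Q) >= n:
            raise ValueError("lag count must be smaller than the trace length")
        self.n_samples_ = n
        self.target_rows_ = np.arange(max(self.J, self.Q), n)
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"I[t-{s}]" for s in range(self.J + 1)]
        names += [f"S[t-{q}]" for q in range(1, self.Q + 1)]
        return np.asarray(names, dtype=object)

    @property
    def n_output_features_(self) -> int:
        return self.J + 1 + self.Q

    def transform(self, X) -> np.ndarray:
        X = _as_channels(X)
        if X.shape[0] != self.n_samples_:
            raise ValueError("transform input must match the fitted length")
        I, S = X[:, 0], X[:, 1]
        rows = self.target_rows_
        cols = [I[rows - s] for s in range(self.J + 1)]
        cols += [S[rows - q] for q in range(1, self.Q + 1)]
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Raised-cosine design
# ---------------------------------------------------------------------------

class RaisedCosineFeatures(TransformerMixin, BaseEstimator):
    """Elementwise products of channels with log-stretched raised-cosine bumps.

    Bump j is a half-period cosine in the stretched time a(t) = log(t + psi):
    ``0.5 * (1 + cos((a - c_j) * pi / (2 * dc)))`` on ``|a - c_j| <= 2 dc``,
    zero outside.  Centers c_j are equally spaced in a-space, so the bumps sum
    to a constant away from the edges while concentrating resolution at early
    times.

    Parameters
    ----------
    n_bumps : int or pair of ints
        Bumps per channel (a pair allows an odd total column count).
    log_offset : float
        The stretch parameter psi > 0; larger values make the spacing more
        nearly linear.
    """

    def __init__(self, n_bumps=10, log_offset: float = 1.0):
        self.n_bumps = n_bumps
        self.log_offset = log_offset

    def _bumps_per_channel(self, n_channels):
        if np.ndim(self.n_bumps) == 0:
            counts = [int(self.n_bumps)] * n_channels
        else:
            counts = [int(k) for k in self.n_bumps]
            if len(counts) != n_channels:
                raise ValueError("one bump count per channel required")
        if any(k < 0 for k in counts) or sum(counts) < 1:
            raise ValueError("bump counts must be nonnegative with at least "
                             "one bump overall")
        return counts

    def fit(self, X, y=None):
        X = _as_channels(X)
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")
        self.n_samples_ = X.shape[0]
        self.n_channels_ = X.shape[1]
        self.bumps_per_channel_ = self._bumps_per_channel(X.shape[1])
        return self

    def _basis(self, k: int) -> np.ndarray:
        if k == 0:
            return np.zeros((self.n_samples_, 0))
        t = np.arange(1, self.n_samples_ + 1, dtype=float)
        a = np.log(t + self.log_offset)
        lo, hi = a[0], a[-1]
        if k == 1:
            centers = np.array([(lo + hi) / 2.0])
            dc = (hi - lo) / 2.0 or 1.0
        else:
            centers = np.linspace(lo, hi, k)
            dc = centers[1] - centers[0]
        arg = (a[:, None] - centers[None, :]) * np.pi / (2.0 * dc)
        return np.where(np.abs(arg) <= np.pi, 0.5 * (1.0 + np.cos(arg)), 0.0)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        out = []
        for c, k in enumerate(self.bumps_per_channel_):
            out += [f"ch{c}:rc{j}" for j in range(1, k + 1)]
        return np.asarray(out, dtype=object)

    @property
    def n_output_features_(self) -> int:
        return int(sum(self.bumps_per_channel_))

    def transform(self, X) -> np.ndarray:
        X = _as_channels(X)
        if X.shape != (self.n_samples_, self.n_channels_):
            raise ValueError("transform input must match the fitted shape")
        blocks = []
        for c, k in enumerate(self.bumps_per_channel_):
            blocks.append(self._basis(k) * X[:, c][:, None])
        return np.hstack(blocks)


# ---------------------------------------------------------------------------
# Thin functional wrappers returning labeled designs
# ---------------------------------------------------------------------------

def _two_channel(I, S) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    if I.shape != S.shape or I.ndim != 1:
        raise ValueError("I and S must be 1-d sequences of equal length")
    return np.column_stack([I, S])


def lagged_design(I, S, J: int, Q: int) -> DesignMatrix:
    """Lagged design over current lags 0..J and spike-history lags 1..Q."""
    tf = LaggedFeatures(J=J, Q=Q).fit(_two_channel(I, S))
    return DesignMatrix(
        X=tf.transform(_two_channel(I, S)),
        column_labels=list(tf.get_feature_names_out()),
        target_rows=tf.target_rows_,
    )


def fourier_feature_design(I, S_prev, n_freq="full") -> DesignMatrix:
    """Fourier-feature design over the current and lagged-spike channels."""
    X = _two_channel(I, S_prev)
    tf = FourierFeatures(n_freq=n_freq, channel_names=["I", "S"]).fit(X)
    return DesignMatrix(
        X=tf.transform(X),
        column_labels=list(tf.get_feature_names_out()),
        target_rows=np.arange(X.shape[0]),
    )


def raised_cosine_design(I, S_prev, k_bumps, log_offset: float = 1.0) -> DesignMatrix:
    """Raised-cosine design; ``k_bumps`` bumps per channel (int or pair)."""
    X = _two_channel(I, S_prev)
    tf = RaisedCosineFeatures(n_bumps=k_bumps, log_offset=log_offset).fit(X)
    return DesignMatrix(
        X=tf.transform(X),
        column_labels=list(tf.get_feature_names_out()),
        target_rows=np.arange(X.shape[0]),
    )


def pca_design(lagged: DesignMatrix, k: int):
    """First k principal-component scores of the centered lagged design.

    Returns ``(design, explained_variance_fraction)`` where the fraction is
    cumulative over the k retained components.
    """
    max_rank = min(lagged.X.shape)
    if not 1 <= k <= max_rank:
        raise ValueError(f"component count must be in [1, {max_rank}]")
    pca = PCA(n_components=k, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(lagged.X)
    design = DesignMatrix(
        X=scores,
        column_labels=[f"pc{j}" for j in range(1, k + 1)],
        target_rows=lagged.target_rows,
    )
    return design, float(np.sum(pca.explained_variance_ratio_))
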