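"""Singular spectrum analysis (SSA) of rest-activity time series.

SSA decomposes a series ``x(n)``, n = 1..N, into additive components in
three steps:

1. *Embedding*: a window of length ``L`` (2 <= L <= N/2) slides over the
   series with unit step, stacking the K = N - L + 1 lagged windows into
   the Hankel trajectory matrix ``X`` (every ascending anti-diagonal is
   constant).
2. *SVD*: ``X = sum_k sigma_k u_k v_k^T`` splits the trajectory matrix
   exactly into rank-1 elementary matrices with singular values
   ``sigma_1 >= sigma_2 >= ...``; the partial variances
   ``lambda_k = sigma_k^2`` measure each component's share of the total
   ``lambda_tot = ||X||_F^2``.
3. *Diagonal averaging*: each elementary matrix is mapped back to a
   series ``g_k(n)`` by averaging its anti-diagonals, giving the exact
   additive decomposition ``x(n) = sum_k sigma_k g_k(n)``.

For 1-week actigraphy at 1-min epochs the window is one circadian
period, L = 1440 min, so the first component is the slowly varying
trend (mesor), the near-degenerate pair (2, 3) is the circadian
oscillation, and the tail k >= 4 holds ultradian fluctuations whose
ordered fractional partial variances form the scree diagram analysed by
:mod:`chronossa.scaling`.

Unlike Fourier analysis the basis is data-adaptive; in the limit
L -> N/2 SSA converges to Fourier spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hankel
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ActigraphySeries

__all__ = [
    "SingularSpectrum",
    "SSADecomposition",
    "ComponentGrouping",
    "embed",
    "decompose",
    "diagonal_average",
    "diagonal_weights",
    "scree",
    "w_correlation",
    "estimate_component_period",
    "find_circadian_pair",
]

#: Sentinel period for non-oscillating (trend) components.
TREND_PERIOD = np.inf


def _as_series_array(x) -> np.ndarray:
    if isinstance(x, ActigraphySeries):
        return x.counts
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    return arr


def embed(x, L: int) -> np.ndarray:
    """Trajectory matrix: K x L Hankel matrix of lagged windows.

    Row i (0-based) is ``(x_i, ..., x_{i+L-1})``; element [i, j] is
    ``x_{i+j}``, so every ascending anti-diagonal is constant.
    """
    x = _as_series_array(x)
    N = x.size
    if not 2 <= L <= N // 2:
        raise ValueError(f"window L={L} must satisfy 2 <= L <= N/2 (N={N})")
    K = N - L + 1
    return hankel(x[:K], x[K - 1 :])


def diagonal_weights(N: int, L: int) -> np.ndarray:
    """Number of trajectory-matrix entries on each anti-diagonal.

    ``w_n = min(n, L, K, N - n + 1)`` for n = 1..N (returned 0-based);
    these are also the multiplicities of each sample in the embedding
    and the weights of the w-correlation inner product.
    """
    K = N - L + 1
    n = np.arange(1, N + 1)
    return np.minimum.reduce([n, np.full(N, L), np.full(N, K), N - n + 1]).astype(float)


def diagonal_average(matrix: np.ndarray) -> np.ndarray:
    """Map a K x L matrix to a length N = K + L - 1 series.

    Entry n of the output is the mean of matrix elements with
    i + j = n (0-based).  On a Hankel matrix this inverts :func:`embed`
    exactly; it is linear, so summing the diagonal averages of all
    elementary matrices returns the original series.
    """
    matrix = np.asarray(matrix, dtype=float)
    K, L = matrix.shape
    N = K + L - 1
    out = np.zeros(N)
    for i in range(K):
        out[i : i + L] += matrix[i]
    return out / diagonal_weights(N, L)


def _rank1_diagonal_average(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    # anti-diagonal sums of the outer product u v^T are the full linear
    # convolution of u and v
    conv = fftconvolve(u, v)
    return conv / w


@dataclass
class SSADecomposition:
    """Result of an SSA decomposition.

    ``components`` holds the unit-normalised series ``g_k(n)`` (row k);
    the physical contribution of component k is ``sigma_k * g_k`` and
    ``x = sum_k sigma_k g_k`` exactly when ``r`` is the full rank.
    """

    L: int
    K: int
    r: int
    singular_values: np.ndarray
    components: np.ndarray
    frobenius_sq: float
    epoch_minutes: float = 1.0

    @property
    def N(self) -> int:
        return self.K + self.L - 1

    @property
    def partial_variances(self) -> np.ndarray:
        """lambda_k = sigma_k^2, non-increasing."""
        return self.singular_values**2

    @property
    def lambda_tot(self) -> float:
        """Total variance of the trajectory phase space, ||X||_F^2."""
        return self.frobenius_sq

    def reconstruct(self, indices=None) -> np.ndarray:
        """Sum of physical components sigma_k g_k over ``indices`` (0-based)."""
        if indices is None:
            indices = range(self.r)
        idx = np.asarray(list(indices), dtype=int)
        return (self.singular_values[idx, None] * self.components[idx]).sum(axis=0)


@dataclass
class ComponentGrouping:
    """Assignment of SSA components to trend / circadian / ultradian.

    Indices are 0-based: the default is trend {0}, circadian {1, 2}
    (the near-degenerate sine/cosine pair) and ultradian k >= 3.
    """

    trend: tuple = (0,)
    circadian: tuple = (1, 2)
    ultradian: tuple = field(default_factory=tuple)

    def validate(self, r: int) -> "ComponentGrouping":
        ultra = self.ultradian or tuple(
            k for k in range(r) if k not in self.trend and k not in self.circadian
        )
        sets = [set(self.trend), set(self.circadian), set(ultra)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("component groups must be disjoint")
        if set().union(*sets) != set(range(r)):
            raise ValueError("component groups must cover 0..r-1")
        return ComponentGrouping(tuple(self.trend), tuple(self.circadian), ultra)


class SingularSpectrum(BaseEstimator, TransformerMixin):
    """SSA decomposition as a scikit-learn transformer.

    Parameters
    ----------
    window : int, default=1440
        Embedding window ``L`` in samples; for 1-min epochs the default
        is one circadian period (24 h).  Only (quasi-)periodicities
        with mean length up to about ``L`` are resolved into separate
        components; slower ones are absorbed into the trend.
    r_max : int or None, default=None
        Number of leading components to keep.  ``None`` keeps the full
        rank ``min(L, K)``; the scree power-law fits only need the
        leading decades, so a truncated decomposition of long series is
        much cheaper.

    Attributes
    ----------
    singular_values_ : ndarray of shape (r,)
        ``sigma_k``, non-increasing.
    partial_variances_ : ndarray of shape (r,)
        ``lambda_k = sigma_k^2``.
    lambda_total_ : float
        Squared Frobenius norm of the trajectory matrix (sum of *all*
        lambda_k, including any truncated ones).
    components_ : ndarray of shape (r, N)
        Unit-normalised component series ``g_k(n)``.

    Examples
    --------
    >>> x = np.sin(2 * np.pi * np.arange(2880) / 288)
    >>> dec = SingularSpectrum(window=288).fit(x).decomposition_
    >>> float(dec.partial_variances[:2].sum() / dec.lambda_tot) > 0.999
    True
    """

    def __init__(self, window: int = 1440, r_max: int | None = None):
        self.window = window
        self.r_max = r_max

    def fit(self, X, y=None):
        """Decompose the series ``X`` (1-D array or ActigraphySeries)."""
        epoch = X.epoch_minutes if isinstance(X, ActigraphySeries) else 1.0
        x = _as_series_array(X)
        N = x.size
        L = int(self.window)
        traj = embed(x, L)
        K = N - L + 1
        full_rank = min(L, K)
        r = full_rank if self.r_max is None else min(int(self.r_max), full_rank)
        if r < 1:
            raise ValueError("r_max must be at least 1")
        u, s, vt = np.linalg.svd(traj, full_matrices=False)
        if not np.all(np.isfinite(s)):
            raise np.linalg.LinAlgError("SVD of the trajectory matrix did not converge")
        w = diagonal_weights(N, L)
        comps = np.empty((r, N))
        for k in range(r):
            comps[k] = _rank1_diagonal_average(u[:, k], vt[k], w)
        self.decomposition_ = SSADecomposition(
            L=L,
            K=K,
            r=r,
            singular_values=s[:r].copy(),
            components=comps,
            frobenius_sq=float(np.sum(s**2)),
            epoch_minutes=epoch,
        )
        self.singular_values_ = self.decomposition_.singular_values
        self.partial_variances_ = self.decomposition_.partial_variances
        self.lambda_total_ = self.decomposition_.lambda_tot
        self.components_ = self.decomposition_.components
        self.n_features_in_ = N
        return self

    def transform(self, X):
        """Decompose ``X`` with the fitted hyperparameters.

        Returns the (r, N) matrix of physical components sigma_k g_k.
        """
        check_is_fitted(self, "decomposition_")
        dec = SingularSpectrum(window=self.window, r_max=self.r_max).fit(X).decomposition_
        return dec.singular_values[:, None] * dec.components

    def reconstruct(self, indices=None) -> np.ndarray:
        """Partial reconstruction over 0-based component ``indices``."""
        check_is_fitted(self, "decomposition_")
        return self.decomposition_.reconstruct(indices)


def decompose(series, L: int = 1440, r_max: int | None = None) -> SSADecomposition:
    """Functional SSA front end: embed, SVD, diagonal averaging."""
    return SingularSpectrum(window=L, r_max=r_max).fit(series).decomposition_


def scree(decomposition: SSADecomposition) -> np.ndarray:
    """Ordered fractional partial variances lambda_k / lambda_tot."""
    return decomposition.partial_variances / decomposition.lambda_tot


def w_correlation(decomposition: SSADecomposition) -> np.ndarray:
    """Weighted correlation matrix between component series.

    The inner product weights ``w_n`` count how often sample n appears
    in the trajectory matrix; well-separated components (e.g. the
    circadian pair vs the trend) have w-correlations near zero.  Rows
    for zero-norm components are set to 0 (diagonal forced to 1).
    """
    dec = decomposition
    w = diagonal_weights(dec.N, dec.L)
    G = dec.components
    gram = (G * w) @ G.T
    norms = np.sqrt(np.diag(gram))
    ok = norms > 0
    denom = np.outer(np.where(ok, norms, 1.0), np.where(ok, norms, 1.0))
    corr = gram / denom
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def estimate_component_period(g, epoch_minutes: float = 1.0) -> float:
    """Mean period of a component from its zero crossings.

    The mean-centred series crosses zero twice per cycle, so the mean
    period is twice the mean spacing between successive crossings
    (equivalently ``2 N P / #crossings`` away from the edges, but
    unbiased when the series starts or ends on a crossing).  Components
    with fewer than 2 crossings are non-oscillating and labelled trend
    (period = inf).
    """
    g = _as_series_array(g)
    z = g - g.mean()
    # crossing positions: starts of exact-zero runs plus midpoints of
    # adjacent opposite-sign samples
    iszero = z == 0
    run_starts = np.flatnonzero(iszero & ~np.r_[False, iszero[:-1]])
    sign_change = np.flatnonzero((z[:-1] * z[1:] < 0))
    positions = np.sort(np.concatenate([run_starts.astype(float), sign_change + 0.5]))
    if positions.size < 2:
        return TREND_PERIOD
    mean_spacing = (positions[-1] - positions[0]) / (positions.size - 1)
    return 2.0 * mean_spacing * epoch_minutes


def find_circadian_pair(
    decomposition: SSADecomposition,
    target_period: float = 1440.0,
    degeneracy_tol: float = 0.2,
    period_tol: float = 0.2,
) -> tuple[int, int]:
    """Locate the near-degenerate circadian sine/cosine pair.

    Scans successive partial-variance pairs (lambda_k, lambda_{k+1})
    for the first one that is nearly degenerate
    (|lambda_k - lambda_{k+1}| / lambda_k < ``degeneracy_tol``) and
    whose component periods both fall within ``period_tol`` of the
    target circadian period.  Falls back to the canonical pair (1, 2)
    (0-based) when no pair qualifies, e.g. when the trend splits.
    """
    lam = decomposition.partial_variances
    for k in range(decomposition.r - 1):
        if lam[k] == 0:
            break
        if (lam[k] - lam[k + 1]) / lam[k] < degeneracy_tol:
            periods = [
                estimate_component_period(
                    decomposition.components[j], decomposition.epoch_minutes
                )
                for j in (k, k + 1)
            ]
            if all(
                np.isfinite(p) and abs(p - target_period) / target_period < period_tol
                for p in periods
            ):
                return (k, k + 1)
    return (1, 2)
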