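"""Intradaily variability (IV) and the IV(P) resampling curve.

Classic IV is the variance of the first differences of an activity
series, traditionally resampled to P = 60 min bins, relative to the
variance of the series itself:

    IV = [ sum_{n=2..N} (X_n - X_{n-1})^2 / (N - 1) ]
         / [ sum_{n=1..N} (X_n - <X>)^2 / N ]

(the numerator uses an N-1 divisor, the denominator N; both conventions
are kept exactly).  Treating the resampling interval P as a free
parameter gives the curve IV(P).  Because the numerator and the
denominator each depend on P in their own way, the curve used here
fixes the denominator to the variance of the *original* series x(n),
which is a constant in P:

    IV(P) = Var(X_P') / Var(x)

The legacy normalisation Var(X_P') / Var(X_P) remains available via
``denominator_convention="resampled_variance"`` for comparison.

Resampling uses bin means (not sums) so the resampled series stays on
the counts/min scale of x and the fixed denominator remains
commensurable across P; trailing samples that do not fill a bin are
dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ActigraphySeries

__all__ = ["IVCurve", "resample", "iv_classic", "iv_curve", "default_p_grid"]


@dataclass
class IVCurve:
    """IV(P) evaluated on an ascending grid of resampling intervals."""

    P_values: np.ndarray
    iv: np.ndarray
    denominator_convention: str

    def __post_init__(self):
        if len(self.P_values) != len(self.iv):
            raise ValueError("P_values and iv must have equal length")


def resample(series: ActigraphySeries, P: float) -> ActigraphySeries:
    """Rebin a series to epoch ``P`` minutes by bin means.

    ``P`` must be an integer multiple of the input epoch.  A trailing
    partial bin is dropped (with a warning), never padded, to avoid an
    artificial step in the differenced series.
    """
    ratio = P / series.epoch_minutes
    if P < series.epoch_minutes or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"P={P} must be an integer multiple of the epoch ({series.epoch_minutes})"
        )
    k = int(round(ratio))
    n_bins, leftover = divmod(series.n_samples, k)
    if leftover:
        warnings.warn(
            f"dropping {leftover} trailing samples that do not fill a P={P} bin",
            stacklevel=2,
        )
    binned = series.counts[: n_bins * k].reshape(n_bins, k).mean(axis=1)
    return ActigraphySeries(
        subject_id=series.subject_id,
        group=series.group,
        start_clock=series.start_clock,
        epoch_minutes=float(P),
        counts=binned,
        meta=dict(series.meta),
    )


def _iv_numerator(x: np.ndarray) -> float:
    """Variance of the first differences with the N-1 divisor."""
    return float(np.sum(np.diff(x) ** 2) / (x.size - 1))


def _population_variance(x: np.ndarray) -> float:
    return float(np.sum((x - x.mean()) ** 2) / x.size)


def iv_classic(series: ActigraphySeries) -> float:
    """Intradaily variability of the series at its own epoch.

    For the traditional measure, resample to P = 60 min first.  The
    series must be non-constant and have at least 3 samples.
    """
    x = series.counts
    if x.size < 3:
        raise ValueError("IV needs at least 3 samples")
    denom = _population_variance(x)
    if denom == 0:
        raise ValueError("constant series: IV undefined (zero variance)")
    return _iv_numerator(x) / denom


def default_p_grid(epoch_minutes: float = 1.0, n_points: int = 40) -> np.ndarray:
    """Log-spaced resampling grid 1-600 min including the canonical P=60.

    Values are snapped to integer multiples of the epoch and
    deduplicated; the range covers both the ultradian (~20 min) and
    circadian (~500 min) maxima of interest.
    """
    raw = np.geomspace(epoch_minutes, 600.0, n_points)
    snapped = np.unique(np.maximum(1, np.round(raw / epoch_minutes)).astype(int))
    grid = set(snapped * epoch_minutes)
    grid.add(60.0)
    return np.array(sorted(grid))


def iv_curve(
    series: ActigraphySeries,
    P_values=None,
    denominator_convention: str = "original_variance",
) -> IVCurve:
    """Evaluate IV(P) over a grid of resampling intervals."""
    if denominator_convention not in ("original_variance", "resampled_variance"):
        raise ValueError(f"unknown denominator convention {denominator_convention!r}")
    if P_values is None:
        P_values = default_p_grid(series.epoch_minutes)
    P_values = np.asarray(P_values, dtype=float)
    var_x = _population_variance(series.counts)
    if var_x == 0:
        raise ValueError("constant series: IV undefined (zero variance)")
    values = np.empty(P_values.size)
    for i, P in enumerate(P_values):
        xp = resample(series, P).counts
        if xp.size < 3:
            raise ValueError(f"P={P}: fewer than 3 resampled bins")
        num = _iv_numerator(xp)
        if denominator_convention == "original_variance":
            values[i] = num / var_x
        else:
            var_p = _population_variance(xp)
            if var_p == 0:
                raise ValueError(f"P={P}: resampled series constant")
            values[i] = num / var_p
    return IVCurve(P_values=P_values, iv=values, denominator_convention=denominator_convention)
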