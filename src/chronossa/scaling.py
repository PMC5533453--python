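"""Power-law scaling of the ultradian scree tail.

In healthy rest-activity data the ordered fractional partial variances
of the ultradian SSA components (k >= 4) decay as a single power law
``lambda_k ~ 1/k^gamma`` with gamma near 1 — a 1/f-like signature of
many activity processes at multiple time scales.  Excess variability
concentrated near 60-90-min periods (the basic rest-activity cycle
band, scree ranks around log10 k = 1.5 for a 24 h window at 1-min
epochs) breaks the single law into a crossover between a shallower
exponent gamma_1 at larger scales and a steeper gamma_2 at smaller
scales.

Exponents are ordinary least-squares slopes of log10 lambda_k vs
log10 k, without binning (the rank grid is already dense in log space
over the fitted decades).  Ranks k are 1-based and include the trend
and circadian components, so the ultradian fits start at k = 4.
Printed default ranges: single law 0.78 <= log10 k <= 3.0, crossover
pre-range [0.8, 1.5] and post-range [1.6, 2.0], significance band
[1.4, 1.6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssa import SSADecomposition, estimate_component_period

__all__ = [
    "ScalingFit",
    "fit_power_law",
    "single_fit",
    "crossover_fit",
    "band_fraction",
    "band_to_frequency",
    "SINGLE_RANGE",
    "PRE_RANGE",
    "POST_RANGE",
    "BAND_RANGE",
]

SINGLE_RANGE = (0.78, 3.0)
PRE_RANGE = (0.8, 1.5)
POST_RANGE = (1.6, 2.0)
BAND_RANGE = (1.4, 1.6)


@dataclass
class ScalingFit:
    """Power-law exponents of a scree diagram.

    ``mode`` is ``"single"`` (one exponent ``gamma``) or ``"crossover"``
    (``gamma1`` before and ``gamma2`` after the crossover rank).
    ``band_fraction`` is the summed fractional partial variance over
    the significance band log10 k in [1.4, 1.6].
    """

    mode: str
    gamma: float | None = None
    gamma1: float | None = None
    gamma2: float | None = None
    r_squared: float | None = None
    r_squared1: float | None = None
    r_squared2: float | None = None
    band_fraction: float | None = None

    @property
    def crossover_magnitude(self) -> float:
        if self.mode != "crossover":
            return 0.0
        return self.gamma2 - self.gamma1


def _range_mask(n: int, log10k_range) -> np.ndarray:
    lo, hi = log10k_range
    k = np.arange(1, n + 1)
    logk = np.log10(k)
    return (logk >= lo) & (logk <= hi)


def fit_power_law(partial_variances, log10k_range=SINGLE_RANGE) -> tuple[float, float]:
    """OLS power-law fit lambda_k ~ 1/k^gamma over a log10 k range.

    Returns ``(gamma, r_squared)`` where gamma is the negated slope of
    the log-log regression.  Normalising the partial variances (e.g. by
    lambda_tot) shifts the intercept only, never the exponent.
    """
    lam = np.asarray(partial_variances, dtype=float)
    mask = _range_mask(lam.size, log10k_range)
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 scree ranks in log10 k range {log10k_range}, have {int(mask.sum())}"
        )
    lam_sel = lam[mask]
    if np.any(lam_sel <= 0):
        raise ValueError("partial variances in the fit range must be positive")
    logk = np.log10(np.arange(1, lam.size + 1)[mask])
    loglam = np.log10(lam_sel)
    slope, intercept = np.polyfit(logk, loglam, 1)
    fitted = slope * logk + intercept
    sst = np.sum((loglam - loglam.mean()) ** 2)
    r2 = 1.0 - np.sum((loglam - fitted) ** 2) / sst if sst > 0 else 1.0
    return float(-slope), float(r2)


def band_fraction(partial_variances, log10k_range=BAND_RANGE) -> float:
    """Summed fractional partial variance over a log10 k band."""
    lam = np.asarray(partial_variances, dtype=float)
    mask = _range_mask(lam.size, log10k_range)
    return float(lam[mask].sum() / lam.sum())


def crossover_fit(
    partial_variances,
    pre_range=PRE_RANGE,
    post_range=POST_RANGE,
    band_range=BAND_RANGE,
) -> ScalingFit:
    """Fit separate exponents before and after the crossover.

    ``gamma1`` covers the larger scales (smaller k) and ``gamma2`` the
    smaller scales; an exact single power law gives gamma1 = gamma2.
    """
    if pre_range[1] > post_range[0]:
        raise ValueError("crossover fit ranges must not overlap")
    g1, r21 = fit_power_law(partial_variances, pre_range)
    g2, r22 = fit_power_law(partial_variances, post_range)
    return ScalingFit(
        mode="crossover",
        gamma1=g1,
        gamma2=g2,
        r_squared1=r21,
        r_squared2=r22,
        band_fraction=band_fraction(partial_variances, band_range),
    )


def single_fit(partial_variances, log10k_range=SINGLE_RANGE) -> ScalingFit:
    """Fit one exponent over the whole ultradian range."""
    g, r2 = fit_power_law(partial_variances, log10k_range)
    return ScalingFit(
        mode="single",
        gamma=g,
        r_squared=r2,
        band_fraction=band_fraction(partial_variances),
    )


def band_to_frequency(
    decomposition: SSADecomposition, k_range: tuple[int, int]
) -> tuple[float, float]:
    """Physical mean-period range (minutes) of scree ranks in ``k_range``.

    ``k_range`` is 1-based inclusive.  Uses the zero-crossing mean
    period of each component; raises if every component in the range is
    trend-labelled (no finite period).
    """
    lo, hi = k_range
    if not 1 <= lo <= hi <= decomposition.r:
        raise ValueError(f"k_range {k_range} out of bounds for r={decomposition.r}")
    periods = [
        estimate_component_period(decomposition.components[k - 1], decomposition.epoch_minutes)
        for k in range(lo, hi + 1)
    ]
    finite = [p for p in periods if np.isfinite(p)]
    if not finite:
        raise ValueError("all components in the range are trend-labelled")
    return float(min(finite)), float(max(finite))
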