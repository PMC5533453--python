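"""Day-to-day circadian parameters from the SSA reconstruction.

The trend component (mesor) and the circadian pair of an SSA
decomposition together describe a circadian cycle whose mesor,
amplitude, acrophase and period may all drift from day to day —
information a single cosinor fit averages away.  This module reads the
per-day parameters directly off the reconstructed components:

* acrophase_d: clock position (degrees after midnight) of the d-th
  local maximum of the circadian series, maxima at least 18 h apart so
  ultradian leakage cannot create spurious daily peaks;
* period_d: spacing in minutes between successive maxima (D-1 values);
* amplitude_d: half the max-min range of the circadian series between
  the two minima bracketing maximum d;
* mesor_d: mean of the trend component over calendar day d.

Acrophases are unwrapped (no +/-360 deg jumps) so a drifting rhythm
shows a linear trend rather than wrap artefacts.  Day-to-day summary
statistics use population (divide-by-n) moments: SD, CV = SD/mean,
skewness m3/m2^(3/2) and Pearson kurtosis m4/m2^2 (Gaussian -> 3,
platykurtic < 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import MINUTES_PER_DAY, ActigraphySeries
from .ssa import ComponentGrouping, SSADecomposition

__all__ = [
    "DailyCircadianSeries",
    "circadian_reconstruction",
    "daily_parameters",
    "day_to_day_stats",
    "ssa_r_squared",
]


def circadian_reconstruction(
    decomposition: SSADecomposition, grouping: ComponentGrouping | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split the decomposition into (trend, circadian) series.

    Trend is the sum of sigma_k g_k over the trend group (default the
    leading component) and circadian over the circadian pair (default
    components 2 and 3, 0-based 1 and 2).  Together with the remaining
    ultradian components they reproduce the input exactly.
    """
    grouping = (grouping or ComponentGrouping()).validate(decomposition.r)
    if not grouping.circadian:
        raise ValueError("circadian group must not be empty")
    trend = decomposition.reconstruct(grouping.trend)
    circ = decomposition.reconstruct(grouping.circadian)
    return trend, circ


@dataclass
class DailyCircadianSeries:
    """Per-day circadian parameters and their variability summaries.

    ``acrophase_deg`` is unwrapped; ``period_min`` has one value per
    pair of successive maxima.  ``edge_flags`` marks days whose maximum
    sits within 2 h of the series boundary, where diagonal-averaging
    edge distortion makes the reconstruction less reliable.
    """

    mesor: np.ndarray
    amplitude: np.ndarray
    acrophase_deg: np.ndarray
    period_min: np.ndarray
    edge_flags: np.ndarray
    summaries: dict = field(default_factory=dict)
    ssa_r_squared: float | None = None

    @property
    def n_days(self) -> int:
        return int(self.acrophase_deg.size)


def day_to_day_stats(values) -> dict:
    """Mean, SD, CV, skewness and kurtosis of a per-day parameter.

    Population (divide-by-n) moments throughout; kurtosis is the
    Pearson ratio m4/m2^2 so a Gaussian gives 3 and a linear trend
    pushes the value below 3.  Needs >= 2 values (>= 4 for Skew/Kurt,
    reported as nan otherwise); CV is nan when the mean is 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for variability statistics")
    mean = float(v.mean())
    m2 = float(np.mean((v - mean) ** 2))
    sd = float(np.sqrt(m2))
    cv = sd / mean if mean != 0 else float("nan")
    if v.size >= 4 and m2 > 0:
        m3 = float(np.mean((v - mean) ** 3))
        m4 = float(np.mean((v - mean) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = float("nan")
        kurt = float("nan")
    return {"mean": mean, "sd": sd, "cv": cv, "skew": skew, "kurt": kurt}


def _bracketing(positions: np.ndarray, idx: int, lo: int, hi: int) -> tuple[int, int]:
    left = positions[positions < idx]
    right = positions[positions > idx]
    return (int(left.max()) if left.size else lo, int(right.min()) if right.size else hi)


def daily_parameters(
    trend: np.ndarray,
    circadian: np.ndarray,
    epoch_minutes: float = 1.0,
    start_clock: float = 0.0,
    min_separation_hours: float = 18.0,
    edge_margin_hours: float = 2.0,
) -> DailyCircadianSeries:
    """Extract per-day mesor, amplitude, acrophase and period.

    See the module docstring for the exact reading conventions.  Raises
    if fewer than two circadian maxima are found.
    """
    trend = np.asarray(trend, dtype=float)
    circadian = np.asarray(circadian, dtype=float)
    if trend.shape != circadian.shape or trend.ndim != 1:
        raise ValueError("trend and circadian must be 1-D arrays of equal length")
    N = circadian.size
    if N * epoch_minutes < 2 * MINUTES_PER_DAY:
        raise ValueError("series must span at least 2 days")
    sep = int(round(min_separation_hours * 60.0 / epoch_minutes))
    maxima, _ = find_peaks(circadian, distance=sep)
    if maxima.size < 2:
        raise ValueError("no circadian cycle detected (fewer than 2 maxima)")
    minima, _ = find_peaks(-circadian, distance=sep)

    t = start_clock + epoch_minutes * np.arange(N)
    # unwrapped acrophase: absolute peak times mapped to degrees with the
    # whole-day part removed day by day, keeping the drift continuous
    peak_minutes = t[maxima]
    clock = np.mod(peak_minutes, MINUTES_PER_DAY) / MINUTES_PER_DAY * 360.0
    acro = np.degrees(np.unwrap(np.radians(clock)))

    period = np.diff(peak_minutes)

    amp = np.empty(maxima.size)
    for d, m in enumerate(maxima):
        lo, hi = _bracketing(minima, m, 0, N - 1)
        seg = circadian[lo : hi + 1]
        amp[d] = 0.5 * (seg.max() - seg.min())

    n_days_cal = int(np.ceil((t[-1] + epoch_minutes) / MINUTES_PER_DAY))
    day_idx = (t // MINUTES_PER_DAY).astype(int)
    mesor = np.array(
        [trend[day_idx == d].mean() for d in range(n_days_cal) if np.any(day_idx == d)]
    )

    margin = edge_margin_hours * 60.0 / epoch_minutes
    edge = (maxima < margin) | (maxima > N - 1 - margin)

    out = DailyCircadianSeries(
        mesor=mesor,
        amplitude=amp,
        acrophase_deg=acro,
        period_min=period,
        edge_flags=edge,
    )
    out.summaries = {
        "mesor": day_to_day_stats(mesor),
        "amplitude": day_to_day_stats(amp),
        "acrophase_deg": day_to_day_stats(acro),
        "period_min": day_to_day_stats(period) if period.size >= 2 else None,
    }
    return out


def ssa_r_squared(series: ActigraphySeries | np.ndarray, trend, circadian) -> float:
    """Coefficient of determination of the SSA circadian model.

    R^2 = 1 - Var(x - y)/Var(x) with y = trend + circadian; comparable
    with the cosinor R^2 and typically larger because the SSA model
    follows the day-to-day variability the cosine averages away.
    """
    x = series.counts if isinstance(series, ActigraphySeries) else np.asarray(series, float)
    y = np.asarray(trend, float) + np.asarray(circadian, float)
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant series: R^2 undefined")
    return float(1.0 - np.sum((x - y) ** 2) / sst)
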