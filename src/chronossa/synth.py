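"""Synthetic actigraphy cohort generator.

Emulates 1-week wrist actigraphy at 1-min epochs: nonnegative movement
counts bounded by a device ceiling (default 3000 counts/min), a
circadian cosine with mesor ~216 and amplitude ~178 counts/min peaking
mid-afternoon, a 6-8 h nightly trough, day-to-day jitter of amplitude
and acrophase, and an ultradian stochastic component that is either
1/f-like (control-like behaviour, many activity processes at multiple
time scales) or carries an added quasi-periodic oscillation near 90-min
periods (insomnia-like, basic rest-activity cycle band).

The generated signal for subject s is

    x(t) = clip( M_s + A_d cos(2*pi*(t - m0 - d_d)/T) + u(t), 0, ceiling )

with per-day amplitude ``A_d`` (coefficient of variation
``amplitude_day_cv``), per-day acrophase jitter ``d_d`` (SD
``acrophase_day_sd`` degrees, i.i.d. across days), and ultradian term
``u(t)``.  The 1/f component is synthesized by spectral shaping of
white Gaussian noise (amplitude ~ f^(-1/2) so power ~ 1/f at ultradian
frequencies, plateaued below the circadian frequency) scaled to
``noise_scale`` counts/min RMS; in ``brac90`` mode a band-limited
quasi-periodic oscillation around ``brac_period_minutes`` with variance
``brac_relative_power`` times the 1/f variance is added on top.
Night-time rectification of the oscillation emerges from the clip at 0.

Counts are kept as nonnegative reals by default so that noise-free
parameter recovery is exact; set ``integer_counts=True`` to round to
the integer counts an actigraph reports.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MINUTES_PER_DAY, ActigraphySeries, write_actigraphy_csv

__all__ = ["CohortSpec", "generate_subject", "generate_cohort", "write_cohort"]

#: degrees of acrophase per minute of day (360 deg = 1440 min).
DEG_PER_MIN = 360.0 / MINUTES_PER_DAY

#: Fractional spectral width of the quasi-periodic rest-activity
#: oscillation (Gaussian envelope sigma_f / f0).  0.2 spreads the power
#: over periods of roughly 70-120 min around the 90-min centre, matching
#: the 60-90-min band where rest-activity-cycle variability concentrates.
BRAC_RELATIVE_BANDWIDTH = 0.2


@dataclass
class CohortSpec:
    """Parameters of one synthetic group.

    Defaults reproduce a control-like young-adult group: mesor
    216 +/- 56 counts/min across subjects, amplitude 178 counts/min
    with day-to-day CV 0.28, acrophase 232 deg (15:28) with 26 deg
    day-to-day SD, ideal 1440-min period and a 1/f ultradian component
    of 300 counts/min RMS.
    """

    n_subjects: int = 20
    n_days: int = 7
    epoch_minutes: float = 1.0
    mesor_mean: float = 216.0
    mesor_sd: float = 56.0
    amplitude_mean: float = 178.0
    amplitude_day_cv: float = 0.28
    acrophase_mean: float = 232.0
    acrophase_day_sd: float = 26.0
    period_minutes: float = 1440.0
    ultradian_mode: str = "one_over_f"
    brac_period_minutes: float = 90.0
    brac_relative_power: float = 0.3
    noise_scale: float = 300.0
    count_ceiling: float = 3000.0
    burst_rate: float = 0.0
    burst_scale: float = 3.0
    integer_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("n_subjects and n_days must be positive")
        if self.epoch_minutes <= 0 or self.period_minutes <= 0:
            raise ValueError("epoch_minutes and period_minutes must be positive")
        if self.ultradian_mode not in ("one_over_f", "brac90"):
            raise ValueError(f"unknown ultradian_mode {self.ultradian_mode!r}")
        if self.brac_relative_power < 0 or self.noise_scale < 0:
            raise ValueError("power/scale parameters must be nonnegative")
        if not 0 <= self.acrophase_mean < 360:
            raise ValueError("acrophase_mean must lie in [0, 360)")
        n = self.n_days * MINUTES_PER_DAY / self.epoch_minutes
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "n_days * 1440 / epoch_minutes must be an integer number of samples"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.n_days * MINUTES_PER_DAY / self.epoch_minutes))


def _one_over_f(rng: np.random.Generator, n: int, epoch_minutes: float) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise.

    The 1/f amplitude law applies at ultradian frequencies; below the
    circadian frequency the envelope plateaus so the stochastic term
    does not inject multi-day drift on top of the explicitly modelled
    mesor/circadian structure.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=epoch_minutes)  # cycles per minute
    f_circ = 1.0 / MINUTES_PER_DAY
    shape = np.zeros_like(f)
    shape[1:] = np.maximum(f[1:], f_circ) ** -0.5
    shaped = np.fft.irfft(spec * shape, n)
    return shaped / shaped.std()


def _brac_oscillation(
    rng: np.random.Generator, n: int, epoch_minutes: float, period_minutes: float
) -> np.ndarray:
    """Unit-variance quasi-periodic oscillation near ``period_minutes``.

    Band-limited Gaussian noise: white noise spectrally shaped by a
    Gaussian amplitude envelope centred at f0 = 1/period with width
    ``BRAC_RELATIVE_BANDWIDTH * f0``, i.e. an oscillation that stays
    coherent for a few cycles but wanders in period, as rest-activity
    cycles do.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=epoch_minutes)  # cycles per minute
    f0 = 1.0 / period_minutes
    envelope = np.exp(-0.5 * ((f - f0) / (BRAC_RELATIVE_BANDWIDTH * f0)) ** 2)
    envelope[0] = 0.0
    shaped = np.fft.irfft(spec * envelope, n)
    return shaped / shaped.std()


def generate_subject(spec: CohortSpec, subject_index: int) -> ActigraphySeries:
    """Generate one subject's series; deterministic in (seed, subject_index).

    The injected ground truth (subject mesor, per-day amplitudes and
    acrophases, clipped fraction) is stored in ``series.meta``.
    """
    spec.validate()
    if subject_index < 0:
        raise ValueError("subject_index must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))
    n = spec.n_samples
    t = spec.epoch_minutes * np.arange(n)

    mesor = spec.mesor_mean + spec.mesor_sd * rng.standard_normal()
    mesor = max(mesor, 0.0)
    amp_day = spec.amplitude_mean * (
        1.0 + spec.amplitude_day_cv * rng.standard_normal(spec.n_days)
    )
    amp_day = np.maximum(amp_day, 0.0)
    jitter_min = (
        spec.acrophase_day_sd / DEG_PER_MIN * rng.standard_normal(spec.n_days)
    )

    # phase jitter anchored at each day's peak and linearly interpolated
    # in between: the acrophase AT the peak is exactly the injected one
    # and the phase stays continuous across midnight; the amplitude is
    # piecewise constant per calendar day (its midnight step is small,
    # the cosine being far from its peak there)
    m0 = spec.acrophase_mean / DEG_PER_MIN
    peak_times = m0 + MINUTES_PER_DAY * np.arange(spec.n_days)
    jitter_t = np.interp(t, peak_times, jitter_min)
    day = np.minimum((t // MINUTES_PER_DAY).astype(int), spec.n_days - 1)
    phase_arg = 2.0 * np.pi * (t - m0 - jitter_t) / spec.period_minutes
    signal = mesor + amp_day[day] * np.cos(phase_arg)

    if spec.noise_scale > 0:
        ultra = spec.noise_scale * _one_over_f(rng, n, spec.epoch_minutes)
        if spec.ultradian_mode == "brac90" and spec.brac_relative_power > 0:
            osc = _brac_oscillation(rng, n, spec.epoch_minutes, spec.brac_period_minutes)
            ultra = ultra + spec.noise_scale * np.sqrt(spec.brac_relative_power) * osc
        signal = signal + ultra

    if spec.burst_rate > 0:
        bursts = rng.random(n) < spec.burst_rate
        signal = np.where(
            bursts, signal * (1.0 + rng.exponential(spec.burst_scale, n)), signal
        )

    clipped = (signal < 0) | (signal > spec.count_ceiling)
    counts = np.clip(signal, 0.0, spec.count_ceiling)
    if spec.integer_counts:
        counts = np.round(counts)

    # true time-of-day (deg) of each day's circadian maximum
    drift = spec.period_minutes - MINUTES_PER_DAY
    acro_true = (
        spec.acrophase_mean
        + (jitter_min + drift * np.arange(spec.n_days)) * DEG_PER_MIN
    )
    return ActigraphySeries(
        subject_id=f"s{subject_index:03d}",
        group="",
        start_clock=0.0,
        epoch_minutes=spec.epoch_minutes,
        counts=counts,
        meta={
            "mesor_true": float(mesor),
            "amplitude_day_true": amp_day,
            "acrophase_day_true_deg": acro_true,
            "clipped_fraction": float(clipped.mean()),
            "spec": asdict(spec),
        },
    )


def generate_cohort(
    control_spec: CohortSpec,
    case_spec: CohortSpec,
    labels: tuple[str, str] = ("control", "case"),
) -> list[ActigraphySeries]:
    """Generate a labelled two-group cohort.

    Subject seeds derive reproducibly from each spec's own seed, so the
    two groups are independent streams.
    """
    out = []
    for spec, label in zip((control_spec, case_spec), labels):
        spec.validate()
        for i in range(spec.n_subjects):
            s = generate_subject(spec, i)
            s.subject_id = f"{label}_{i:03d}"
            s.group = label
            out.append(s)
    return out


def write_cohort(cohort: list[ActigraphySeries], out_dir: str | Path) -> Path:
    """Write one CSV per subject plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.subject_id}.csv"
        write_actigraphy_csv(s, out_dir / fname)
        rows.append({"subject_id": s.subject_id, "group": s.group, "file": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
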