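"""Reading and writing actigraphy series and analysis tables.

Everything is plain CSV.  A subject file has two columns, ``timestamp``
(ISO-8601) and ``counts`` (nonnegative integers, one row per epoch); a
cohort is a directory of subject files plus a manifest CSV mapping
``subject_id, group, file``.

The in-memory container is :class:`ActigraphySeries`.  Sample ``n``
(0-based) covers the half-open interval ``[t_n, t_n + P)`` minutes, where
``t_n = start_clock + n * epoch_minutes`` and ``start_clock`` is the
minute-of-day of the first sample (midnight = 0).  All clock quantities
downstream (acrophases, profile minutes) use this midnight reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActigraphySeries",
    "FormatError",
    "read_actigraphy_csv",
    "write_actigraphy_csv",
    "read_manifest",
    "write_results_table",
]

MINUTES_PER_DAY = 1440.0


class FormatError(ValueError):
    """Raised when an input file violates the documented CSV layout."""


@dataclass
class ActigraphySeries:
    """One subject's epoch-based movement-count series.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject.
    group : str
        Group label, e.g. ``"control"`` or ``"case"``.
    start_clock : float
        Minute-of-day of the first sample, in ``[0, 1440)``.
    epoch_minutes : float
        Epoch length ``P`` in minutes (positive).
    counts : numpy.ndarray
        Nonnegative activity counts, length ``N >= 2``.
    meta : dict
        Free-form provenance (e.g. the generator's ground truth).
    """

    subject_id: str
    group: str
    start_clock: float
    epoch_minutes: float
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1-D array with N >= 2")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain missing or non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.epoch_minutes > 0:
            raise ValueError("epoch_minutes must be positive")
        if not 0 <= self.start_clock < MINUTES_PER_DAY:
            raise ValueError("start_clock must lie in [0, 1440)")

    @property
    def n_samples(self) -> int:
        return int(self.counts.size)

    @property
    def duration_minutes(self) -> float:
        return self.n_samples * self.epoch_minutes

    def times(self) -> np.ndarray:
        """Sample times in minutes since midnight of the first day."""
        return self.start_clock + self.epoch_minutes * np.arange(self.n_samples)

    def clock_minutes(self) -> np.ndarray:
        """Minute-of-day of each sample, wrapped to [0, 1440)."""
        return np.mod(self.times(), MINUTES_PER_DAY)


def read_actigraphy_csv(
    path: str | Path, subject_id: str = "", group: str = ""
) -> ActigraphySeries:
    """Read one subject's series from a two-column timestamp/counts CSV.

    The epoch is inferred from the first two timestamps and the start
    clock from the first timestamp's time of day.  Timestamps must be
    strictly increasing and equidistant; missing values and negative
    counts are rejected (no imputation is attempted).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("timestamp", "counts"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["counts"].isna().any() or df["timestamp"].isna().any():
        raise ValueError(f"{path}: missing values are not supported")
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    deltas = np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(float)
    if np.any(deltas <= 0) or not np.allclose(deltas, deltas[0]):
        raise FormatError(f"{path}: timestamps are not strictly equidistant")
    epoch_minutes = deltas[0] / 60.0
    t0 = ts.iloc[0]
    start_clock = t0.hour * 60.0 + t0.minute + t0.second / 60.0
    return ActigraphySeries(
        subject_id=subject_id or path.stem,
        group=group,
        start_clock=start_clock,
        epoch_minutes=epoch_minutes,
        counts=df["counts"].to_numpy(dtype=float),
    )


def write_actigraphy_csv(
    series: ActigraphySeries, path: str | Path, start_date: str = "2000-01-01"
) -> Path:
    """Write a series to CSV, regenerating timestamps from the start clock."""
    path = Path(path)
    origin = pd.Timestamp(start_date) + pd.Timedelta(minutes=series.start_clock)
    stamps = origin + pd.to_timedelta(
        series.epoch_minutes * np.arange(series.n_samples), unit="m"
    )
    counts = series.counts
    as_int = counts.astype(int)
    out = pd.DataFrame(
        {
            "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
            # integer counts stay integers for a lossless round trip
            "counts": as_int if np.array_equal(as_int, counts) else counts,
        }
    )
    out.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> list[ActigraphySeries]:
    """Load a cohort from a manifest CSV (subject_id, group, file)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "group", "file"):
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        out.append(
            read_actigraphy_csv(fpath, subject_id=str(row.subject_id), group=str(row.group))
        )
    return out


def write_results_table(
    records: Sequence[Mapping[str, object]], path: str | Path
) -> Path:
    """Write homogeneous per-subject result records to CSV.

    Column order follows the first record; every record must carry
    exactly the same keys.  Floats are written at full precision so a
    read-back reproduces the values bit-for-bit (via repr round trip).
    """
    path = Path(path)
    records = list(records)
    if not records:
        pd.DataFrame().to_csv(path, index=False)
        return path
    keys = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != keys:
            raise ValueError(f"record {i} has keys differing from the first record")
    df = pd.DataFrame(records, columns=keys)
    df.to_csv(path, index=False, float_format="%.17g")
    return path
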