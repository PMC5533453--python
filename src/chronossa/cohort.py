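"""Group-level statistics for actigraphy cohorts.

Two-group comparisons of per-subject rhythm parameters use the
rank-based Kruskal-Wallis test (chi-square approximation with tie
correction, 1 degree of freedom for two groups; an exact permutation
null is available for very small samples).  The minute-wise mean 24 h
activity profile is compared minute by minute at raw alpha = 0.05 —
1440 uncorrected tests, a deliberately liberal convention that flags
transition bands (rest-to-wake, wake-to-rest) between groups; an
optional Benjamini-Hochberg flag is provided for a corrected view.
Agreement between the cosinor and SSA descriptions of the circadian
cycle is quantified per subject by Pearson's r and Spearman's rho
between the two model series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .cosinor import CosinorFit
from .io import MINUTES_PER_DAY, ActigraphySeries

__all__ = [
    "GroupComparison",
    "ProfileComparison",
    "kruskal_wallis",
    "mean_24h_profile",
    "cosinor_ssa_agreement",
    "compare_parameters",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Kruskal-Wallis comparison of one parameter between two groups."""

    parameter: str
    group_summaries: dict  # label -> (mean, sd)
    H: float
    p_value: float
    significant: bool

    def __post_init__(self):
        self.significant = bool(self.p_value < ALPHA)


def _kw_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n1 = pooled.size, a.size
    r1, r2 = ranks[:n1].sum(), ranks[n1:].sum()
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / (n - n1)) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_wallis(
    sample_a,
    sample_b,
    parameter: str = "",
    labels: tuple[str, str] = ("control", "case"),
    method: str = "chi2",
    n_resamples: int = 10000,
    seed: int | None = None,
) -> GroupComparison:
    """Two-group Kruskal-Wallis test.

    ``method="chi2"`` uses the standard chi-square approximation with
    1 df; ``method="permutation"`` estimates the null by label
    permutation (exhaustive when feasible within ``n_resamples``),
    recommended only below ~8 subjects per group.  Samples in which
    every value is identical give H = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    summaries = {
        labels[0]: (float(a.mean()), float(a.std())),
        labels[1]: (float(b.mean()), float(b.std())),
    }
    if np.unique(np.concatenate([a, b])).size == 1:
        return GroupComparison(parameter, summaries, 0.0, 1.0, False)
    h = _kw_statistic(a, b)
    if method == "chi2":
        p = float(stats.chi2.sf(h, df=1))
    elif method == "permutation":
        pooled = np.concatenate([a, b])
        n, n1 = pooled.size, a.size
        from math import comb

        if comb(n, n1) <= n_resamples:
            null = [
                _kw_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
                for idx in combinations(range(n), n1)
            ]
        else:
            rng = np.random.default_rng(seed)
            null = []
            for _ in range(n_resamples):
                perm = rng.permutation(pooled)
                null.append(_kw_statistic(perm[:n1], perm[n1:]))
        null = np.asarray(null)
        p = float(np.mean(null >= h - 1e-12))
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(parameter, summaries, float(h), p, p < ALPHA)


@dataclass
class ProfileComparison:
    """Minute-of-day mean profiles per group with per-minute tests."""

    minute_of_day: np.ndarray
    group_means: dict  # label -> ndarray over minute bins
    p_values: np.ndarray
    significant: np.ndarray
    intervals: list = field(default_factory=list)  # (start hh:mm, end hh:mm)


def _hhmm(minute: float) -> str:
    m = int(round(minute))
    return f"{m // 60:02d}:{m % 60:02d}"


def _daily_profile(series: ActigraphySeries) -> np.ndarray:
    ppd = MINUTES_PER_DAY / series.epoch_minutes
    if abs(ppd - round(ppd)) > 1e-9:
        raise ValueError("epoch must divide the day")
    ppd = int(round(ppd))
    n_days, rem = divmod(series.n_samples, ppd)
    if rem:
        raise ValueError("series must span an integer number of days")
    prof = series.counts.reshape(n_days, ppd).mean(axis=0)
    shift = int(round(series.start_clock / series.epoch_minutes))
    return np.roll(prof, shift)  # align bin 0 with midnight


def mean_24h_profile(
    cohort: list[ActigraphySeries],
    alpha: float = ALPHA,
    bh_correct: bool = False,
) -> ProfileComparison:
    """Per-group mean 24 h profile with minute-wise group comparison.

    Each subject contributes its across-day mean profile (subjects,
    not days, are the replication unit); each minute-of-day bin is then
    compared across groups with Kruskal-Wallis.  Contiguous runs of
    significant minutes are reported as (start, end) clock intervals.
    """
    if not cohort:
        raise ValueError("empty cohort")
    epochs = {s.epoch_minutes for s in cohort}
    if len(epochs) != 1:
        raise ValueError("all series must share the same epoch")
    epoch = epochs.pop()
    groups = sorted({s.group for s in cohort})
    if len(groups) != 2:
        raise ValueError("profile comparison needs exactly 2 groups")
    profiles = {g: [] for g in groups}
    for s in cohort:
        profiles[s.group].append(_daily_profile(s))
    for g, rows in profiles.items():
        if len(rows) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
    mats = {g: np.vstack(rows) for g, rows in profiles.items()}
    ppd = mats[groups[0]].shape[1]
    minute_of_day = epoch * np.arange(ppd)

    p_values = np.empty(ppd)
    for j in range(ppd):
        a, b = mats[groups[0]][:, j], mats[groups[1]][:, j]
        if np.unique(np.concatenate([a, b])).size == 1:
            p_values[j] = 1.0
        else:
            p_values[j] = stats.chi2.sf(_kw_statistic(a, b), df=1)
    if bh_correct:
        significant = _benjamini_hochberg(p_values, alpha)
    else:
        significant = p_values < alpha

    intervals = []
    start = None
    for j in range(ppd):
        if significant[j] and start is None:
            start = j
        elif not significant[j] and start is not None:
            intervals.append((_hhmm(minute_of_day[start]), _hhmm(minute_of_day[j])))
            start = None
    if start is not None:
        intervals.append((_hhmm(minute_of_day[start]), "24:00"))

    return ProfileComparison(
        minute_of_day=minute_of_day,
        group_means={g: m.mean(axis=0) for g, m in mats.items()},
        p_values=p_values,
        significant=significant,
        intervals=intervals,
    )


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        out[order[: np.max(np.flatnonzero(passed)) + 1]] = True
    return out


def cosinor_ssa_agreement(
    series: ActigraphySeries,
    cosinor_fit: CosinorFit,
    ssa_model: np.ndarray,
) -> tuple[float, float]:
    """Pearson r and Spearman rho between the two circadian models.

    ``ssa_model`` is the SSA trend + circadian reconstruction; the
    cosinor model series is evaluated on the subject's own time grid.
    """
    t = series.times()
    w = 2.0 * np.pi / cosinor_fit.T
    y_cos = cosinor_fit.M + cosinor_fit.A * np.cos(w * t + np.radians(cosinor_fit.phi))
    y_ssa = np.asarray(ssa_model, dtype=float)
    if y_ssa.shape != y_cos.shape:
        raise ValueError("model series lengths differ")
    if np.ptp(y_cos) == 0 or np.ptp(y_ssa) == 0:
        raise ValueError("constant model series: correlation undefined")
    r = float(stats.pearsonr(y_cos, y_ssa).statistic)
    rho = float(stats.spearmanr(y_cos, y_ssa).statistic)
    return r, rho


def compare_parameters(
    records_by_group: dict, parameters: list[str], **kw_kwargs
) -> list[GroupComparison]:
    """Kruskal-Wallis comparison for each named per-subject parameter.

    ``records_by_group`` maps a group label to a list of per-subject
    mappings (e.g. cosinor fit records as dicts).
    """
    labels = sorted(records_by_group)
    if len(labels) != 2:
        raise ValueError("need exactly 2 groups")
    out = []
    for param in parameters:
        a = [float(rec[param]) for rec in records_by_group[labels[0]]]
        b = [float(rec[param]) for rec in records_by_group[labels[1]]]
        out.append(
            kruskal_wallis(a, b, parameter=param, labels=(labels[0], labels[1]), **kw_kwargs)
        )
    return out
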