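"""Behavioral characterization of drinking events.

Given per-event start clock times and durations, this module computes the
standard ethology summaries for faucet-drinking behavior:

* hourly event counts and mean durations over the lights-on day;
* "drinking power" per clock hour — ``count x mean duration`` in seconds, a
  combined frequency-duration load measure — and each hour's percentage of
  the daily total;
* stratification of hourly power into feeding-related thirst hours versus
  the remaining lights-on hours;
* per-pig-day summaries (counts, totals, mean/max/std durations, first and
  last event hour);
* inter-animal comparison of daily event counts (Kruskal-Wallis preferred,
  one-way ANOVA for reference, Shapiro-Wilk normality per group);
* an illness-indicator rule flagging days that deviate from an individual's
  healthy-baseline median.

Dispersion statistics use the population denominator ``n`` throughout: a
pig's six observed days are treated as the complete record of the monitored
period, not a sample from a longer one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import time
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Clock hours with expected feeding-driven thirst (feedings ~07:00 and ~13:00).
FEEDING_HOURS = frozenset({8, 9, 13, 14, 15})
#: Remaining lights-on hours used as the non-feeding contrast.
NON_FEEDING_HOURS = frozenset({6, 7, 10, 11, 12, 16, 17, 18})
#: Lights-on window of the housing facility.
LIGHTS_ON = (time(6, 30), time(18, 30))


# ---------------------------------------------------------------------------
# Hourly summaries and drinking power
# ---------------------------------------------------------------------------

def _event_hours_durations(events) -> tuple[np.ndarray, np.ndarray]:
    hours, durs = [], []
    for ev in events:
        if getattr(ev, "start_clock", None) is None:
            raise ValueError("events must carry a start clock time for hourly binning")
        hours.append(ev.start_clock.hour)
        durs.append(float(ev.duration_s))
    return np.asarray(hours, dtype=int), np.asarray(durs, dtype=float)


def hourly_summary(events, lights_on: tuple[time, time] = LIGHTS_ON) -> pd.DataFrame:
    """Event count, mean and total duration per clock hour of the day.

    An event belongs wholly to the clock hour of its start.  All 24 hours are
    reported; hours without events hold zero counts.  Events outside the
    lights-on window are kept but reported with a warning.
    """
    table = pd.DataFrame(
        {"events": 0, "mean_duration_s": 0.0, "total_duration_s": 0.0},
        index=pd.RangeIndex(24, name="hour"),
    )
    if not events:
        return table
    hours, durs = _event_hours_durations(events)
    outside = (hours < lights_on[0].hour) | (hours > lights_on[1].hour)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} event(s) start outside the lights-on window")
    for h in np.unique(hours):
        sel = durs[hours == h]
        table.loc[h, "events"] = sel.size
        table.loc[h, "mean_duration_s"] = sel.mean()
        table.loc[h, "total_duration_s"] = sel.sum()
    return table


def hourly_from_counts(counts: Mapping[int, int],
                       mean_durations: Mapping[int, float]) -> pd.DataFrame:
    """Build an hourly summary directly from per-hour counts and mean durations."""
    table = pd.DataFrame(
        {"events": 0, "mean_duration_s": 0.0, "total_duration_s": 0.0},
        index=pd.RangeIndex(24, name="hour"),
    )
    for h, n in counts.items():
        table.loc[h, "events"] = int(n)
        table.loc[h, "mean_duration_s"] = float(mean_durations[h])
        table.loc[h, "total_duration_s"] = n * float(mean_durations[h])
    return table


@dataclass(frozen=True)
class PowerTable:
    """Per-hour drinking power with its overall row.

    ``per_hour`` has columns events, mean_duration_s, power_s, pct over the
    hours with at least one event; ``overall_mean_s`` is total power divided
    by total events.
    """

    per_hour: pd.DataFrame
    total_events: int
    total_power_s: float

    @property
    def overall_mean_s(self) -> float:
        return self.total_power_s / self.total_events

    @property
    def observed_hours(self) -> list[int]:
        return list(self.per_hour.index)


def power_table(hourly: pd.DataFrame) -> PowerTable:
    """Drinking power per hour: ``power_h = n_h x mean-duration_h`` seconds.

    Power is always recomputed from count and mean duration; the percentage
    column is each hour's share of the total power.  Hours with zero events
    are excluded from the table (they carry no power).
    """
    observed = hourly[hourly["events"] > 0].copy()
    if observed.empty:
        raise ValueError("power table requires at least one event")
    observed["power_s"] = observed["events"] * observed["mean_duration_s"]
    total_power = float(observed["power_s"].sum())
    observed["pct"] = 100.0 * observed["power_s"] / total_power
    return PowerTable(
        per_hour=observed[["events", "mean_duration_s", "power_s", "pct"]],
        total_events=int(observed["events"].sum()),
        total_power_s=total_power,
    )


@dataclass(frozen=True)
class StratifiedPower:
    """Mean hourly power share per hour stratum, relative to the all-hours mean."""

    feeding_mean_pct: float
    non_feeding_mean_pct: float
    all_hours_mean_pct: float

    @property
    def feeding_relative_pct(self) -> float:
        return 100.0 * self.feeding_mean_pct / self.all_hours_mean_pct

    @property
    def non_feeding_relative_pct(self) -> float:
        return 100.0 * self.non_feeding_mean_pct / self.all_hours_mean_pct


def stratify_power(power: PowerTable,
                   feeding_hours: Iterable[int] = FEEDING_HOURS,
                   other_hours: Iterable[int] = NON_FEEDING_HOURS) -> StratifiedPower:
    """Contrast feeding-related thirst hours against the remaining hours.

    Each stratum's statistic is the mean of its hours' power percentages;
    the all-hours reference mean is ``100 / n_observed_hours``, so a stratum
    at 100 % relative power drinks no more per hour than the day overall.
    """
    feeding, other = set(feeding_hours), set(other_hours)
    if feeding & other:
        raise ValueError(f"hour sets overlap: {sorted(feeding & other)}")
    pct = power.per_hour["pct"]
    missing = (feeding | other) - set(pct.index)
    if missing:
        warnings.warn(f"hours {sorted(missing)} have no events; ignored in stratification")
    return StratifiedPower(
        feeding_mean_pct=float(pct.reindex(sorted(feeding)).dropna().mean()),
        non_feeding_mean_pct=float(pct.reindex(sorted(other)).dropna().mean()),
        all_hours_mean_pct=100.0 / len(pct),
    )


# ---------------------------------------------------------------------------
# Daily summaries and descriptive statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailySummary:
    """Key drinking metrics for one pig-day."""

    pig_id: str
    day: int
    events: int
    total_s: float
    mean_s: float
    max_s: float
    std_s: float
    first_hour: float | None
    last_hour: float | None

    @property
    def total_min(self) -> float:
        return self.total_s / 60.0


def daily_summary(events, pig_id: str = "pig", day: int = 1) -> DailySummary:
    """Summarize one pig-day of events; an empty day yields a zero-count row."""
    if not events:
        return DailySummary(pig_id, day, 0, 0.0, 0.0, 0.0, 0.0, None, None)
    hours, durs = _event_hours_durations(events)
    clock_frac = np.array(
        [ev.start_clock.hour + ev.start_clock.minute / 60.0 for ev in events]
    )
    return DailySummary(
        pig_id=pig_id, day=day, events=int(durs.size),
        total_s=float(durs.sum()), mean_s=float(durs.mean()),
        max_s=float(durs.max()), std_s=float(durs.std(ddof=0)),
        first_hour=float(clock_frac.min()), last_hour=float(clock_frac.max()),
    )


def descriptive_stats(daily_counts: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-pig mean, median, population std and range of daily event counts."""
    rows = {}
    for pig, counts in daily_counts.items():
        arr = np.asarray(counts, dtype=float)
        if arr.size < 1:
            raise ValueError(f"{pig}: at least one day required")
        rows[pig] = {
            "n_days": arr.size,
            "mean": arr.mean(),
            "median": float(np.median(arr)),
            "std": arr.std(ddof=0),
            "min": arr.min(),
            "max": arr.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Inter-pig tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected midranks) and chi-square p-value."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p on the group decomposition."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(a.var() == 0 for a in arrays):
        grand = np.concatenate(arrays)
        if np.ptp(grand) == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance: F is undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def normality_test(group: Sequence[float]) -> float:
    """Shapiro-Wilk p-value for one group (3 <= n <= 50)."""
    arr = np.asarray(group, dtype=float)
    if not 3 <= arr.size <= 50:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 50, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("constant sample: normality test undefined")
    return float(stats.shapiro(arr).pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """Descriptive statistics plus omnibus tests on per-pig daily counts."""

    stats: pd.DataFrame
    h: float
    h_pvalue: float
    f: float
    f_pvalue: float
    normality_pvalues: dict[str, float]


def compare_groups(daily_counts: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Full inter-pig comparison of daily drinking event counts."""
    groups = list(daily_counts.values())
    h, hp = kruskal_wallis(groups)
    f, fp = one_way_anova(groups)
    normality = {pig: normality_test(c) for pig, c in daily_counts.items()}
    return GroupComparison(stats=descriptive_stats(daily_counts),
                           h=h, h_pvalue=hp, f=f, f_pvalue=fp,
                           normality_pvalues=normality)


# ---------------------------------------------------------------------------
# Illness indicator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IllnessRule:
    """Deviation-from-baseline rule for a single animal.

    ``absolute`` mode flags a day when the count deviates from the baseline
    median by more than ``k`` baseline standard deviations; ``relative`` mode
    when it deviates by more than fraction ``r`` of the baseline median.
    Each pig acts as its own control: the baseline must come from a healthy
    window of the same animal.
    """

    k: float = 2.0
    r: float = 0.4

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not 0.0 < self.r < 1.0:
            raise ValueError("r must lie in (0, 1)")


def illness_flags(daily_counts: Sequence[float],
                  baseline_days: Sequence[int],
                  rule: IllnessRule = IllnessRule(),
                  mode: str = "absolute") -> np.ndarray:
    """Flag days deviating from the individual's healthy-baseline median.

    ``baseline_days`` are indices into ``daily_counts`` (>= 3 of them);
    baseline days themselves are also scored, so a flagged baseline day
    signals an unsuitable baseline.
    """
    counts = np.asarray(daily_counts, dtype=float)
    base = counts[np.asarray(baseline_days, dtype=int)]
    if base.size < 3:
        raise ValueError("baseline window must span at least 3 days")
    m_b = float(np.median(base))
    s_b = float(base.std(ddof=0))
    dev = np.abs(counts - m_b)
    if mode == "absolute":
        return dev > rule.k * s_b
    if mode == "relative":
        return dev > rule.r * m_b
    raise ValueError(f"unknown mode {mode!r}; use 'absolute' or 'relative'")
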