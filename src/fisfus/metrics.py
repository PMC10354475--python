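"""Temporal metrics: experienced group size, activity, time-of-day binning,
activity-normalized event rates and moving-average smoothing.

The experienced group size of a partition with group sizes N_1..N_n is
sum(N_i^2) / sum(N_i): the average group size from the perspective of the
individuals rather than of an observer (each group weighted by its own
membership). For four individuals split 3 + 1 it is (3*3 + 1*1)/4 = 2.5.

Activity is the population mean Euclidean displacement per sampling
interval. Clock-of-day aggregation uses a configurable local timezone;
minute-of-day means average across all days of the study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .events import EventList
from .grouping import GroupTimeline, Partition
from .trajectories import TrajectorySet

logger = logging.getLogger("fisfus")

__all__ = [
    "experienced_group_size",
    "experienced_series",
    "step_displacements",
    "population_activity",
    "local_clock",
    "minute_of_day_mean",
    "events_per_minute",
    "normalize_events_by_activity",
    "moving_average",
    "TimeOfDayBins",
    "BinSummary",
    "bin_distribution",
]

MINUTES_PER_DAY = 1440


def experienced_group_size(sizes) -> float:
    """Average group size as experienced by an individual: sum(N_i^2)/sum(N_i).

    ``sizes`` is either an iterable of group sizes or a :class:`Partition`.
    """
    if isinstance(sizes, Partition):
        sizes = sizes.sizes()
    arr = np.asarray(list(sizes), dtype=float)
    if arr.size == 0:
        raise DataError("experienced group size is undefined for an empty partition")
    if (arr < 1).any():
        raise DataError("group sizes must be >= 1")
    return float((arr * arr).sum() / arr.sum())


def experienced_series(timeline: GroupTimeline) -> np.ndarray:
    """Experienced group size at every step (NaN where nobody is present)."""
    out = np.full(timeline.n_steps, np.nan)
    for t in range(timeline.n_steps):
        sizes = timeline.group_sizes(t)
        sizes = [s for s in sizes if s > 0]
        n_unassigned = int((timeline.labels[t] == -2).sum())
        sizes.extend([1] * n_unassigned)
        if sizes:
            out[t] = experienced_group_size(sizes)
    return out


def step_displacements(traj: TrajectorySet) -> np.ndarray:
    """Euclidean distance each individual moved during each grid interval.

    Shape ``(n_individuals, n_steps)``; the value at step ``k`` is the
    displacement over the interval ending at ``k`` (so step 0 is NaN), and
    NaN wherever either endpoint position is missing.
    """
    d = np.full((traj.n_individuals, traj.n_steps), np.nan)
    if traj.n_steps > 1:
        diff = traj.xy[:, 1:, :] - traj.xy[:, :-1, :]
        d[:, 1:] = np.hypot(diff[..., 0], diff[..., 1])
    return d


def population_activity(traj: TrajectorySet) -> np.ndarray:
    """Mean displacement per interval across individuals, per step."""
    disp = step_displacements(traj)
    n = np.isfinite(disp).sum(axis=0)
    total = np.nansum(np.where(np.isfinite(disp), disp, 0.0), axis=0)
    return np.divide(total, n, out=np.full(traj.n_steps, np.nan), where=n > 0)


def local_clock(t0: float, dt: float, n_steps: int, tz: str = "UTC") -> pd.DatetimeIndex:
    """Local-timezone timestamps of every grid step."""
    times = pd.to_datetime(t0 + np.arange(n_steps) * dt, unit="s", utc=True)
    return times.tz_convert(ZoneInfo(tz))


def minute_of_day_mean(values, t0: float, dt: float, tz: str = "UTC") -> np.ndarray:
    """Mean of a per-step series for each local minute of the day.

    Returns a length-1440 vector; minutes with no observations are NaN.
    """
    values = np.asarray(values, dtype=float)
    clock = local_clock(t0, dt, values.size, tz)
    minute = clock.hour * 60 + clock.minute
    out = np.full(MINUTES_PER_DAY, np.nan)
    series = pd.Series(values).groupby(np.asarray(minute)).mean()
    out[series.index.to_numpy()] = series.to_numpy()
    return out


def events_per_minute(
    events: EventList,
    traj: TrajectorySet,
    tz: str = "UTC",
    kind: str | None = None,
) -> np.ndarray:
    """Mean number of events per local minute of the day, across days.

    For each of the 1440 minutes, the total number of events (optionally of
    one ``kind``) whose step falls in that minute is divided by the number
    of distinct days on which that minute was observed in the trajectory
    grid. Minutes never observed are NaN. Fissions and fusions are pooled by
    default; pass ``kind`` to split.
    """
    clock = local_clock(traj.t0, traj.dt, traj.n_steps, tz)
    minute = np.asarray(clock.hour * 60 + clock.minute)
    days = pd.DataFrame({"minute": minute, "date": clock.date}).drop_duplicates()
    n_days = days.groupby("minute").size()

    counts = np.zeros(MINUTES_PER_DAY)
    for ev in events:
        if kind is not None and ev.kind != kind:
            continue
        counts[minute[ev.step]] += 1

    out = np.full(MINUTES_PER_DAY, np.nan)
    idx = n_days.index.to_numpy()
    out[idx] = counts[idx] / n_days.to_numpy()
    return out


def normalize_events_by_activity(event_counts, activity) -> np.ndarray:
    """Events divided by mean motion, minute by minute.

    Minutes with zero or missing activity yield NaN (flagged with a warning):
    an event rate per metre of motion is undefined when nothing moved.
    """
    events = np.asarray(event_counts, dtype=float)
    act = np.asarray(activity, dtype=float)
    if events.shape != act.shape:
        raise ConfigError("event and activity series must share their minute grid")
    bad = ~np.isfinite(act) | (act == 0)
    if (bad & np.isfinite(events) & (events > 0)).any():
        logger.warning(
            "%d minutes have events but zero/missing activity; rate set to NaN",
            int((bad & (events > 0)).sum()),
        )
    out = np.full(events.shape, np.nan)
    ok = ~bad & np.isfinite(events)
    out[ok] = events[ok] / act[ok]
    return out


def moving_average(series, window: int = 10) -> np.ndarray:
    """Centered moving average, window truncated at the edges, NaNs excluded."""
    if window < 1:
        raise ConfigError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


@dataclass(frozen=True)
class TimeOfDayBins:
    """Local-clock bins partitioning the 24 h cycle.

    Each bin is a half-open [start, end) hour range (wrapping past
    midnight). The defaults follow approximate dawn/dusk at the study site:
    night 22-5, morning 5-11, midday 11-16, evening 16-22; high activity is
    morning plus evening, low activity night plus midday.
    """

    edges: dict = field(
        default_factory=lambda: {
            "night": (22, 5),
            "morning": (5, 11),
            "midday": (11, 16),
            "evening": (16, 22),
        }
    )
    combined: dict = field(
        default_factory=lambda: {
            "high_activity": ("morning", "evening"),
            "low_activity": ("night", "midday"),
        }
    )

    def __post_init__(self) -> None:
        cover = np.zeros(MINUTES_PER_DAY, dtype=int)
        for start, end in self.edges.values():
            s, e = int(start * 60), int(end * 60)
            if s < e:
                cover[s:e] += 1
            else:
                cover[s:] += 1
                cover[:e] += 1
        if not (cover == 1).all():
            raise ConfigError("time-of-day bins must partition the 24 h cycle")

    def assign(self, minute_of_day: np.ndarray) -> np.ndarray:
        """Bin name for each minute-of-day value."""
        out = np.empty(np.asarray(minute_of_day).shape, dtype=object)
        m = np.asarray(minute_of_day)
        for name, (start, end) in self.edges.items():
            s, e = int(start * 60), int(end * 60)
            sel = (m >= s) & (m < e) if s < e else (m >= s) | (m < e)
            out[sel] = name
        return out


@dataclass(frozen=True)
class BinSummary:
    """Distribution summary of a per-step series within one time-of-day bin."""

    proportions: pd.Series  # integer-rounded value -> relative frequency
    mean: float
    mode: int
    ci_low: float
    ci_high: float
    n: int


def _summarize(values: np.ndarray) -> BinSummary:
    counts = pd.Series(np.rint(values).astype(int)).value_counts().sort_index()
    proportions = counts / counts.sum()
    n = values.size
    mean = float(values.mean())
    if n > 1 and values.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n)
    else:
        half = 0.0
    return BinSummary(
        proportions=proportions,
        mean=mean,
        mode=int(proportions.idxmax()),
        ci_low=mean - half,
        ci_high=mean + half,
        n=n,
    )


def bin_distribution(
    values,
    t0: float,
    dt: float,
    tz: str = "UTC",
    bins: TimeOfDayBins | None = None,
) -> dict[str, BinSummary]:
    """Distribution of a per-step series in each time-of-day bin.

    Returns one :class:`BinSummary` per named bin plus the combined
    high/low-activity bins: a histogram of integer-rounded values as
    proportions summing to 1, the mean, the (integer) mode and a t-based 95%
    confidence interval of the mean over all step observations in the bin.
    Empty bins are flagged with a warning and omitted.
    """
    bins = bins or TimeOfDayBins()
    values = np.asarray(values, dtype=float)
    clock = local_clock(t0, dt, values.size, tz)
    minute = np.asarray(clock.hour * 60 + clock.minute)
    names = bins.assign(minute)
    ok = np.isfinite(values)
    out: dict[str, BinSummary] = {}
    groups: dict[str, np.ndarray] = {
        name: values[ok & (names == name)] for name in bins.edges
    }
    for combo, parts in bins.combined.items():
        groups[combo] = np.concatenate([groups[p] for p in parts]) if parts else np.array([])
    for name, vals in groups.items():
        if vals.size == 0:
            logger.warning("time-of-day bin %r has no observations", name)
            continue
        out[name] = _summarize(vals)
    return out
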