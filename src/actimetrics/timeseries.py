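"""Reading, validation and preprocessing of wrist-accelerometry recordings.

The activity signal analysed throughout the package is ENMO (Euclidean norm
minus one): the per-sample magnitude of triaxial acceleration in g-force,
minus 1 g of gravity, floored at zero.  Recordings arrive either as triaxial
CSV (``timestamp,x,y,z``) or as precomputed ENMO CSV (``timestamp,enmo``);
after gap cleaning they become a :class:`EnmoSeries` — a uniformly sampled
nonnegative series with an absolute start time — on which every downstream
statistic operates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import time as dtime, date as ddate
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActimetricsWarning",
    "NonUniformGridError",
    "DegenerateSeriesError",
    "TriaxialRecord",
    "EnmoSeries",
    "DayNightConfig",
    "CleanResult",
    "compute_enmo",
    "clean_recording",
    "clock_partition",
    "daily_profile",
    "read_recording_csv",
    "write_enmo_csv",
    "write_drop_report",
]

SECONDS_PER_DAY = 86400.0


class ActimetricsWarning(UserWarning):
    """Warning category for all non-fatal data-quality notices."""


class NonUniformGridError(ValueError):
    """Raised when timestamps depart from the expected sampling grid.

    Carries ``index``, the position of the first offending inter-sample gap.
    """

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class DegenerateSeriesError(ValueError):
    """Raised when a statistic is undefined (zero variance, empty bins...)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TriaxialRecord:
    """Raw triaxial acceleration with absolute timestamps.

    Axis values are in g-force.  Timestamps must be strictly increasing and
    all three axis arrays must match their length.  Axis values may be
    signed; only the Euclidean norm matters downstream.
    """

    timestamps: pd.DatetimeIndex
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.timestamps)
        if n == 0:
            raise ValueError("empty record")
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("axis arrays must match timestamp length")
        if n > 1:
            diffs = np.diff(self.timestamps.asi8)
            if np.any(diffs <= 0):
                idx = int(np.argmax(diffs <= 0))
                raise ValueError(
                    f"timestamps not strictly increasing at index {idx + 1}"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    def norm(self) -> np.ndarray:
        """Euclidean norm of the three axes, per sample (g)."""
        return np.sqrt(self.ax ** 2 + self.ay ** 2 + self.az ** 2)


@dataclass
class EnmoSeries:
    """Uniformly sampled nonnegative ENMO series.

    The implied timestamp of sample ``i`` (0-based) is ``start + i*dt``
    seconds.  ``dt`` is the sampling period in seconds (5 s in the kind of
    wrist-accelerometer deployment this package targets).
    """

    start: pd.Timestamp
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.dt = float(self.dt)
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("ENMO values must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def duration_seconds(self) -> float:
        return self.n * self.dt

    def timestamps(self) -> pd.DatetimeIndex:
        """Implied timestamps of every sample."""
        return self.start + pd.to_timedelta(np.arange(self.n) * self.dt, unit="s")

    def clock_seconds(self) -> np.ndarray:
        """Seconds past local midnight for every sample (naive local time)."""
        offset = (self.start - self.start.normalize()).total_seconds()
        return (offset + np.arange(self.n) * self.dt) % SECONDS_PER_DAY


@dataclass(frozen=True)
class DayNightConfig:
    """Clock partition of the 24-h day into two half-open intervals.

    ``[day_start, night_start)`` is day and ``[night_start, day_start)`` is
    night.  Defaults follow the low-activity window commonly seen in ENMO
    averages: night 23:00–06:00, day 06:00–23:00.  Times are naive local
    clock times; no daylight-saving adjustment is applied.
    """

    day_start: dtime = dtime(6, 0)
    night_start: dtime = dtime(23, 0)

    def __post_init__(self) -> None:
        if self.day_start == self.night_start:
            raise ValueError("day_start and night_start must differ")

    @property
    def day_start_seconds(self) -> float:
        t = self.day_start
        return t.hour * 3600 + t.minute * 60 + t.second

    @property
    def night_start_seconds(self) -> float:
        t = self.night_start
        return t.hour * 3600 + t.minute * 60 + t.second

    def is_day(self, clock_seconds: np.ndarray) -> np.ndarray:
        """Boolean day-mask for an array of seconds-past-midnight."""
        d, n = self.day_start_seconds, self.night_start_seconds
        c = np.asarray(clock_seconds)
        if d < n:
            return (c >= d) & (c < n)
        # day interval wraps midnight
        return (c >= d) | (c < n)


@dataclass
class CleanResult:
    """Gap-cleaned series plus the list of calendar dates that were dropped."""

    series: EnmoSeries
    dropped_dates: list[ddate] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ENMO computation
# ---------------------------------------------------------------------------

def _infer_dt(timestamps: pd.DatetimeIndex) -> float:
    diffs = np.diff(timestamps.asi8) / 1e9
    return float(np.median(diffs))


def compute_enmo(record: TriaxialRecord, dt: float | None = None) -> EnmoSeries:
    """Euclidean norm minus one, truncated at zero, on a uniform grid.

    ``values[i] = max(0, sqrt(ax^2 + ay^2 + az^2) - 1)``; the 1 g subtraction
    removes gravity and the truncation keeps the activity signal nonnegative.

    Parameters
    ----------
    record
        Validated triaxial record on a uniform timestamp grid.
    dt
        Sampling period in seconds; inferred as the median inter-sample
        interval when omitted.

    Raises
    ------
    NonUniformGridError
        If any inter-sample interval deviates from ``dt`` by more than 1%.
    """
    if len(record) == 0:
        raise ValueError("empty record")
    ts = record.timestamps
    if dt is None:
        dt = _infer_dt(ts) if len(ts) > 1 else 1.0
    if len(ts) > 1:
        diffs = np.diff(ts.asi8) / 1e9
        off = np.abs(diffs - dt)
        if np.any(off >= dt / 100.0):
            idx = int(np.argmax(off >= dt / 100.0))
            raise NonUniformGridError(
                f"non-uniform sampling at index {idx + 1}: gap "
                f"{diffs[idx]:.6g} s vs expected {dt:.6g} s",
                index=idx + 1,
            )
    values = np.maximum(0.0, record.norm() - 1.0)
    return EnmoSeries(start=ts[0], dt=dt, values=values)


# ---------------------------------------------------------------------------
# Gap cleaning
# ---------------------------------------------------------------------------

def clean_recording(
    data: TriaxialRecord | EnmoSeries | tuple[pd.DatetimeIndex, np.ndarray],
    dt: float | None = None,
) -> CleanResult:
    """Drop every calendar day touched by a sampling gap; splice the rest.

    A gap is an inter-sample interval larger than ``1.5*dt`` (or smaller than
    ``0.5*dt``, which indicates timestamp corruption).  Both calendar days
    adjacent to a gap are dropped in full, as are days wholly absent between
    them; the retained days are concatenated in chronological order into one
    uniform :class:`EnmoSeries`.  Because only whole days are removed, clock
    alignment of the surviving samples is preserved whenever ``dt`` divides
    86400 s.

    Accepts a triaxial record (ENMO computed per sample first), an existing
    series (identity: it is gap-free by construction), or an explicit
    ``(timestamps, enmo_values)`` pair.

    Raises
    ------
    DegenerateSeriesError
        If every day is dropped ("no complete days").
    """
    if isinstance(data, EnmoSeries):
        return CleanResult(series=data, dropped_dates=[])
    if isinstance(data, TriaxialRecord):
        ts = data.timestamps
        values = np.maximum(0.0, data.norm() - 1.0)
    else:
        ts, values = data
        ts = pd.DatetimeIndex(ts)
        values = np.asarray(values, dtype=float)
    if len(ts) == 0:
        raise ValueError("empty record")
    if dt is None:
        dt = _infer_dt(ts) if len(ts) > 1 else 1.0

    dates = ts.normalize()
    dropped: set[pd.Timestamp] = set()
    if len(ts) > 1:
        diffs = np.diff(ts.asi8) / 1e9
        bad = (diffs > 1.5 * dt) | (diffs < 0.5 * dt)
        for i in np.flatnonzero(bad):
            left, right = dates[i], dates[i + 1]
            dropped.add(left)
            dropped.add(right)
            # calendar days wholly absent inside the gap
            day = left + pd.Timedelta(days=1)
            while day < right:
                dropped.add(day)
                day += pd.Timedelta(days=1)

    keep = ~dates.isin(list(dropped)) if dropped else np.ones(len(ts), bool)
    if not np.any(keep):
        raise DegenerateSeriesError("no complete days after gap cleaning")
    if dropped and SECONDS_PER_DAY % dt != 0:
        warnings.warn(
            "dt does not divide 86400 s; clock alignment may drift across "
            "spliced day boundaries",
            ActimetricsWarning,
            stacklevel=2,
        )
    series = EnmoSeries(start=ts[keep][0], dt=dt, values=values[keep])
    dropped_dates = sorted(d.date() for d in dropped)
    return CleanResult(series=series, dropped_dates=dropped_dates)


# ---------------------------------------------------------------------------
# Clock partition and daily profile
# ---------------------------------------------------------------------------

def clock_partition(
    series: EnmoSeries, cfg: DayNightConfig | None = None
) -> tuple[EnmoSeries, EnmoSeries]:
    """Split a series into concatenated daytime and nighttime streams.

    Each sample is assigned by its clock time to the day interval
    ``[day_start, night_start)`` or the complementary night interval; the
    per-day contiguous segments are then concatenated chronologically into
    one day stream and one night stream.  Sample counts are conserved.

    The returned streams carry the parent's ``start``/``dt`` so downstream
    code can see the sampling period, but their implied timestamps are not
    meaningful across splice points — they are intended for statistics such
    as the DFA exponent that only consume the value sequence.
    """
    cfg = cfg or DayNightConfig()
    mask = cfg.is_day(series.clock_seconds())
    day_vals = series.values[mask]
    night_vals = series.values[~mask]
    if day_vals.size == 0 or night_vals.size == 0:
        warnings.warn(
            "clock partition produced an empty member (series shorter than "
            "one day and confined to one interval)",
            ActimetricsWarning,
            stacklevel=2,
        )
    day = EnmoSeries(start=series.start, dt=series.dt, values=day_vals)
    night = EnmoSeries(start=series.start, dt=series.dt, values=night_vals)
    return day, night


def partition_segments(
    series: EnmoSeries, cfg: DayNightConfig | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Maximal contiguous day/night runs, in chronological order.

    Used by the per-day DFA mode, which fits each run separately instead of
    splicing them together.
    """
    cfg = cfg or DayNightConfig()
    mask = cfg.is_day(series.clock_seconds())
    day_runs: list[np.ndarray] = []
    night_runs: list[np.ndarray] = []
    if series.n == 0:
        return day_runs, night_runs
    boundaries = np.flatnonzero(np.diff(mask.astype(int))) + 1
    edges = np.concatenate(([0], boundaries, [series.n]))
    for a, b in zip(edges[:-1], edges[1:]):
        (day_runs if mask[a] else night_runs).append(series.values[a:b])
    return day_runs, night_runs


def daily_profile(series: EnmoSeries, bin_minutes: int = 60) -> pd.DataFrame:
    """Mean ENMO per clock-time bin over the 24-h day, pooled across days.

    Returns a frame with columns ``bin_start_minute`` (0, bin, 2*bin, ...),
    ``mean`` (NaN where a bin received no samples) and ``count``.
    ``bin_minutes`` must divide 1440.
    """
    bin_minutes = int(bin_minutes)
    if bin_minutes <= 0 or 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must be a positive divisor of 1440")
    n_bins = 1440 // bin_minutes
    idx = np.floor(series.clock_seconds() / (bin_minutes * 60.0)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=series.values, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(counts == 0):
        warnings.warn(
            f"{int((counts == 0).sum())} profile bins received no samples",
            ActimetricsWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "bin_start_minute": np.arange(n_bins) * bin_minutes,
            "mean": means,
            "count": counts,
        }
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_recording_csv(path) -> TriaxialRecord | tuple[pd.DatetimeIndex, np.ndarray]:
    """Read a recording CSV in either supported dialect.

    Dialect A (``timestamp,x,y,z``): returns a :class:`TriaxialRecord`.
    Dialect B (``timestamp,enmo``): returns ``(timestamps, enmo)`` ready for
    :func:`clean_recording`.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if {"timestamp", "x", "y", "z"}.issubset(cols):
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        return TriaxialRecord(
            timestamps=ts,
            ax=df["x"].to_numpy(float),
            ay=df["y"].to_numpy(float),
            az=df["z"].to_numpy(float),
        )
    if {"timestamp", "enmo"}.issubset(cols):
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        return ts, df["enmo"].to_numpy(float)
    raise ValueError(
        "unrecognised CSV dialect: expected header timestamp,x,y,z or "
        "timestamp,enmo"
    )


def load_series(path, dt: float | None = None) -> CleanResult:
    """Read a recording CSV and gap-clean it in one step."""
    return clean_recording(read_recording_csv(path), dt=dt)


def write_enmo_csv(series: EnmoSeries, path) -> None:
    """Write a series in dialect B (``timestamp,enmo``)."""
    pd.DataFrame(
        {"timestamp": series.timestamps(), "enmo": series.values}
    ).to_csv(path, index=False)


def write_drop_report(result: CleanResult, path) -> None:
    """Write the dropped-day report as a JSON list of ISO dates."""
    with open(path, "w") as fh:
        json.dump([d.isoformat() for d in result.dropped_dates], fh)
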