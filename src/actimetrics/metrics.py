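"""Interdaily stability and phase-averaged intradaily variability.

IS is the ratio of the between-clock-hour variance of hourly means to the
total (population) variance of the series: 1 for a perfectly repeating daily
pattern, near 0 for structureless data.  IV is the ratio of mean squared
consecutive differences to variance on a subsampled series: near 2 for white
noise, lower for smooth persistent data, and strongly dependent on the
subsampling factor Δ.  The phase-averaged form computes IV on all Δ phase
shifts of the subsampled grid and averages them, so no sample is discarded
whatever Δ is chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .timeseries import ActimetricsWarning, DegenerateSeriesError, EnmoSeries

__all__ = [
    "ISResult",
    "IVResult",
    "IVSweep",
    "interdaily_stability",
    "iv_single_phase",
    "intradaily_variability",
    "iv_sweep",
]

_VAR_EPS = 0.0  # a phase is degenerate iff its variance is exactly zero


@dataclass
class ISResult:
    """Interdaily stability with its hourly decomposition."""

    is_value: float
    hourly_means: np.ndarray  # mean per clock hour, index 0 = 00:00-01:00
    overall_mean: float
    n_used: np.ndarray  # samples entering each hourly bin


@dataclass
class IVResult:
    """Phase-averaged intradaily variability at one subsampling factor."""

    delta: int
    per_phase: np.ndarray  # IV of each phase; NaN where degenerate
    iv_value: float  # mean over non-degenerate phases
    m: int  # floor(N / delta), length of each phase sequence


@dataclass
class IVSweep:
    """IV as a function of the subsampling factor Δ."""

    deltas: np.ndarray
    iv_values: np.ndarray  # NaN where the statistic was unavailable
    dt: float

    @property
    def seconds(self) -> np.ndarray:
        """Subsampling interval in seconds per Δ."""
        return self.deltas * self.dt

    @property
    def recommended_delta(self) -> int:
        """Δ corresponding to a 5-minute subsampling interval."""
        return max(1, round(300.0 / self.dt))

    @property
    def admissible_band(self) -> tuple[int, int]:
        """Δ range corresponding to 2–10 minutes."""
        return (max(1, round(120.0 / self.dt)), max(1, round(600.0 / self.dt)))


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, EnmoSeries) else np.asarray(series, float)


def interdaily_stability(series: EnmoSeries) -> ISResult:
    """Interdaily stability of an ENMO series.

    Samples are pooled into 24 clock-hour bins across all recorded days
    (partial first/last days contribute to whichever bins they cover).  The
    statistic is

        IS = [ sum_s (mean_s - mean)^2 / 24 ] / [ sum_t (X_t - mean)^2 / N ]

    with ``mean_s`` the mean over all samples whose clock hour is ``s``.
    By the variance decomposition, 0 <= IS <= 1.

    Raises
    ------
    DegenerateSeriesError
        If the series has zero variance, or any clock-hour bin is empty.
    """
    x = series.values
    if x.size < 2:
        raise DegenerateSeriesError("need at least 2 samples")
    hour = np.floor(series.clock_seconds() / 3600.0).astype(int) % 24
    counts = np.bincount(hour, minlength=24)
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0).tolist()
        raise DegenerateSeriesError(f"empty clock-hour bins: {missing}")
    overall = float(x.mean())
    total_var = float(np.mean((x - overall) ** 2))
    if total_var <= _VAR_EPS:
        raise DegenerateSeriesError("degenerate series: zero variance")
    hourly = np.bincount(hour, weights=x, minlength=24) / counts
    num = float(np.mean((hourly - overall) ** 2))
    return ISResult(
        is_value=num / total_var,
        hourly_means=hourly,
        overall_mean=overall,
        n_used=counts,
    )


def iv_single_phase(values) -> float:
    """IV of one ordered sequence: mean squared first difference over variance.

        IV = [ sum_{k>=2} (Y_k - Y_{k-1})^2 / (M-1) ] / [ sum_k (Y_k - Ybar)^2 / M ]

    The denominator is the population variance (divide by M).

    Raises
    ------
    DegenerateSeriesError
        For fewer than 2 values or zero variance.
    """
    y = np.asarray(values, dtype=float)
    m = y.size
    if m < 2:
        raise DegenerateSeriesError("need at least 2 values for IV")
    var = float(np.mean((y - y.mean()) ** 2))
    if var <= _VAR_EPS:
        raise DegenerateSeriesError("degenerate sequence: zero variance")
    num = float(np.mean(np.diff(y) ** 2))
    return num / var


def intradaily_variability(series, delta: int = 1) -> IVResult:
    """Phase-averaged IV at subsampling factor ``delta``.

    The series is split into ``delta`` phase-shifted subsampled sequences
    (phase j takes samples j, j+Δ, j+2Δ, ..., each of length M = floor(N/Δ)),
    :func:`iv_single_phase` is applied to each, and the results averaged.
    Phases with zero variance are excluded with a warning; the average runs
    over the remaining phases.

    Accepts an :class:`~actimetrics.timeseries.EnmoSeries` or a plain array.
    """
    x = _values(series)
    delta = int(delta)
    if delta < 1:
        raise ValueError("delta must be a positive integer")
    m = x.size // delta
    if m < 2:
        raise DegenerateSeriesError(
            f"floor(N/delta) = {m} < 2: series too short for delta={delta}"
        )
    # column j of the (M, delta) view is phase j+1 of the decomposition
    grid = x[: m * delta].reshape(m, delta)
    num = np.sum(np.diff(grid, axis=0) ** 2, axis=0) / (m - 1)
    var = np.mean((grid - grid.mean(axis=0)) ** 2, axis=0)
    ok = var > _VAR_EPS
    per_phase = np.full(delta, np.nan)
    per_phase[ok] = num[ok] / var[ok]
    if not np.any(ok):
        raise DegenerateSeriesError("all phases degenerate (zero variance)")
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} of {delta} phases degenerate; averaged over "
            "the rest",
            ActimetricsWarning,
            stacklevel=2,
        )
    return IVResult(
        delta=delta,
        per_phase=per_phase,
        iv_value=float(np.nanmean(per_phase)),
        m=m,
    )


def iv_sweep(series, deltas=None, dt: float | None = None) -> IVSweep:
    """IV across a grid of subsampling factors (default Δ = 1..720).

    At 5-second sampling the default grid spans intervals of 5 s to 60 min in
    5 s steps.  Per-Δ failures (too-short series, degenerate phases) yield
    NaN entries with a warning rather than aborting the sweep.  The sweep's
    ``recommended_delta`` marks the 5-minute interval, within the admissible
    2–10 minute band.
    """
    x = _values(series)
    if dt is None:
        dt = series.dt if isinstance(series, EnmoSeries) else 1.0
    if deltas is None:
        deltas = np.arange(1, 721)
    deltas = np.asarray(deltas, dtype=int)
    if deltas.size == 0 or np.any(np.diff(deltas) <= 0) or deltas[0] < 1:
        raise ValueError("deltas must be strictly increasing positive integers")
    out = np.full(deltas.size, np.nan)
    failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ActimetricsWarning)
        for i, d in enumerate(deltas):
            try:
                out[i] = intradaily_variability(x, int(d)).iv_value
            except DegenerateSeriesError:
                failures += 1
    if failures:
        warnings.warn(
            f"IV unavailable at {failures} of {deltas.size} subsampling "
            "factors (NaN entries)",
            ActimetricsWarning,
            stacklevel=2,
        )
    return IVSweep(deltas=deltas, iv_values=out, dt=float(dt))
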