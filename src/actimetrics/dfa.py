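"""Detrended fluctuation analysis (DFA) with first-order detrending.

DFA quantifies long-range correlation in a time series.  The series is
mean-centered and cumulatively summed into a profile, the profile is tiled
into non-overlapping segments of length S, a least-squares line is removed
from each segment, and the root-mean-square residual F(S) is computed across
a grid of scales.  For fractal-like series F(S) ~ S^alpha; the scaling
exponent alpha is the slope of an ordinary least-squares fit of log2 F on
log2 S.  alpha equals the Hurst exponent H for stationary series and H + 1
for nonstationary (random-walk-like) series: white noise gives alpha = 0.5,
1/f "pink" noise alpha = 1, a Brownian random walk alpha = 1.5.

The default scale grid is S = round(2^i) for i = 4 to 8 in steps of 0.25
(16 to 256 samples — 1.333 to 21.333 minutes at 5-second sampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .timeseries import (
    ActimetricsWarning,
    DayNightConfig,
    DegenerateSeriesError,
    EnmoSeries,
    clock_partition,
    partition_segments,
)

__all__ = [
    "DFAResult",
    "default_scale_grid",
    "dfa_profile",
    "fluctuation",
    "dfa_exponent",
    "dfa_daynight",
]

MIN_SCALE = 4  # smallest segment with a nonzero residual around a line fit


def default_scale_grid() -> np.ndarray:
    """S = round(2^i), i = 4..8 step 0.25, deduplicated after rounding."""
    i = np.arange(4.0, 8.0 + 1e-9, 0.25)
    return np.unique(np.round(2.0 ** i).astype(int))


@dataclass
class DFAResult:
    """Scale/fluctuation pairs with the fitted scaling exponent."""

    scales: np.ndarray
    fluctuations: np.ndarray
    alpha: float
    r_squared: float
    profile_length: int

    @property
    def hurst(self) -> float:
        """Hurst exponent implied by alpha (H = alpha if stationary, else alpha - 1)."""
        return self.alpha if self.alpha <= 1.0 else self.alpha - 1.0


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, EnmoSeries) else np.asarray(series, float)


def dfa_profile(values) -> np.ndarray:
    """Cumulative sum of the mean-centered series; Z_N = 0 by telescoping."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateSeriesError("need at least 2 samples")
    return np.cumsum(x - x.mean())


def fluctuation(profile, s: int) -> float:
    """Root-mean-square residual of the profile around per-segment line fits.

    Non-overlapping segments of length ``s`` tile the profile from its head;
    a trailing partial segment is discarded.  Within each segment an OLS line
    is fitted against the sample index and the population RMS residual
    (divide by ``s``) taken; F(S) is the root of the mean of the squared
    per-segment residuals.
    """
    z = np.asarray(profile, dtype=float)
    s = int(s)
    if s < MIN_SCALE:
        raise ValueError(f"scale must be >= {MIN_SCALE}")
    k = z.size // s
    if k < 1:
        raise ValueError(f"profile shorter than one segment of length {s}")
    seg = z[: k * s].reshape(k, s)
    xc = np.arange(s) - (s - 1) / 2.0  # centered index, shared by all segments
    denom = float(np.sum(xc ** 2))
    slope = seg @ xc / denom
    resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * xc
    return float(np.sqrt(np.mean(np.mean(resid ** 2, axis=1))))


def dfa_exponent(series, scales=None) -> DFAResult:
    """DFA scaling exponent over a scale grid.

    Computes F(S) for every scale and fits OLS of log2 F(S) on log2 S;
    ``alpha`` is the slope, ``r_squared`` the goodness of that log-log fit.
    Scales with F(S) = 0 (profile exactly linear within every segment) are
    dropped with a warning.

    Raises
    ------
    DegenerateSeriesError
        Constant input (all fluctuations vanish).
    ValueError
        Series shorter than the largest requested scale.
    """
    x = _values(series)
    scales = default_scale_grid() if scales is None else np.unique(
        np.asarray(scales, dtype=int)
    )
    if scales.size < 2:
        raise ValueError("need at least 2 scales for a slope")
    if np.any(scales < MIN_SCALE):
        raise ValueError(f"scales must all be >= {MIN_SCALE}")
    max_s = int(scales[-1])
    if x.size < max_s:
        usable = scales[scales <= x.size]
        hint = int(usable[-1]) if usable.size else None
        raise ValueError(
            f"series of length {x.size} too short for scale {max_s}"
            + (f" (max usable scale {hint})" if hint else "")
        )
    z = dfa_profile(x)
    f = np.array([fluctuation(z, s) for s in scales])
    ok = f > 0
    if not np.any(ok):
        raise DegenerateSeriesError("constant input: all fluctuations vanish")
    if not np.all(ok):
        warnings.warn(
            f"dropping {int((~ok).sum())} scales with zero fluctuation",
            ActimetricsWarning,
            stacklevel=2,
        )
    ls, lf = np.log2(scales[ok].astype(float)), np.log2(f[ok])
    slope, intercept = np.polyfit(ls, lf, 1)
    pred = slope * ls + intercept
    sst = float(np.sum((lf - lf.mean()) ** 2))
    r2 = 1.0 - float(np.sum((lf - pred) ** 2)) / sst if sst > 0 else 1.0
    if not (0.0 < slope < 2.0):
        warnings.warn(
            f"alpha = {slope:.3f} outside the (0, 2) range expected for "
            "realistic activity data",
            ActimetricsWarning,
            stacklevel=2,
        )
    return DFAResult(
        scales=scales,
        fluctuations=f,
        alpha=float(slope),
        r_squared=r2,
        profile_length=x.size,
    )


def dfa_daynight(
    series: EnmoSeries,
    cfg: DayNightConfig | None = None,
    scales=None,
    per_day: bool = False,
) -> tuple[DFAResult | None, DFAResult | None]:
    """Separate DFA exponents for daytime and nighttime readings.

    By default each clock partition is concatenated into a single stream and
    one exponent estimated per stream (splice points across days are a known
    approximation).  With ``per_day=True`` each maximal contiguous run is
    fitted separately and the run exponents averaged, weighted by run length.

    A stream too short for the scale grid yields ``None`` with a warning.
    """
    cfg = cfg or DayNightConfig()
    results: list[DFAResult | None] = []
    if per_day:
        for label, runs in zip(("day", "night"), partition_segments(series, cfg)):
            fits = []
            for run in runs:
                try:
                    fits.append(dfa_exponent(run, scales=scales))
                except (ValueError, DegenerateSeriesError):
                    continue
            if not fits:
                warnings.warn(
                    f"no {label} segment long enough for the scale grid",
                    ActimetricsWarning,
                    stacklevel=2,
                )
                results.append(None)
                continue
            w = np.array([r.profile_length for r in fits], dtype=float)
            w /= w.sum()
            alpha = float(np.sum(w * [r.alpha for r in fits]))
            r2 = float(np.sum(w * [r.r_squared for r in fits]))
            ref = max(fits, key=lambda r: r.profile_length)
            results.append(
                DFAResult(
                    scales=ref.scales,
                    fluctuations=ref.fluctuations,
                    alpha=alpha,
                    r_squared=r2,
                    profile_length=int(sum(r.profile_length for r in fits)),
                )
            )
        return results[0], results[1]

    for label, stream in zip(("day", "night"), clock_partition(series, cfg)):
        try:
            results.append(dfa_exponent(stream, scales=scales))
        except (ValueError, DegenerateSeriesError) as exc:
            warnings.warn(
                f"{label} stream unusable for DFA: {exc}",
                ActimetricsWarning,
                stacklevel=2,
            )
            results.append(None)
    return results[0], results[1]
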