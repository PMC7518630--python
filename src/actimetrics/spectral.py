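"""Periodogram, circadian harmonic band power, PoV, and the cosinor fit.

The proportion of variance (PoV) statistic measures circadian strength as
the fraction of the series' total variance carried by the periodogram in
narrow frequency bands around the circadian fundamental (periods between
23.5 h and 24.5 h — |f| between 1/88200 Hz and 1/84600 Hz) and, for the
harmonic variant, its integer multiples up to the 4th harmonic.  Unlike the
parametric cosinor fit, PoV makes no assumption about the waveform: the
harmonic bands pick up the non-sinusoidal shape of real activity rhythms.

Normalization: band mass is the sum of two-sided periodogram ordinates over
Fourier frequencies in the band, divided by the total two-sided sum, which
by Parseval's theorem equals the series' (population) variance times N.
This makes PoV an exact fraction in [0, 1]; it differs from a denominator
using the N-1 sample variance by a relative factor (N-1)/N, i.e. under 1/N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .timeseries import ActimetricsWarning, DegenerateSeriesError, EnmoSeries

__all__ = [
    "Spectrum",
    "PoVResult",
    "CosinorFit",
    "FUNDAMENTAL_BAND_HOURS",
    "periodogram",
    "band_power",
    "pov",
    "cosinor",
    "cosinor_r2",
]

#: Default period bounds (hours) of the circadian fundamental band.
FUNDAMENTAL_BAND_HOURS = (23.5, 24.5)


@dataclass
class Spectrum:
    """One-sided periodogram of a uniformly sampled series.

    ``power[j] = |sum_t (X_t - Xbar) exp(-i 2 pi f_j t)|^2 / N`` at the
    Fourier frequencies ``f_j = j / (N dt)``, j = 0..floor(N/2).  The value
    at f = 0 is 0 because the mean is removed.  Two-sided sums are recovered
    by doubling interior frequencies (symmetry of the real-input spectrum).
    """

    freqs: np.ndarray  # Hz
    power: np.ndarray
    dt: float  # seconds
    n: int

    @property
    def nyquist(self) -> float:
        """Half the sampling rate, 1/(2 dt) Hz; 0.1 Hz at 5-second sampling."""
        return 1.0 / (2.0 * self.dt)

    def two_sided_weights(self) -> np.ndarray:
        """Multiplicity of each one-sided ordinate on the two-sided grid."""
        w = np.full(self.freqs.size, 2.0)
        w[0] = 1.0
        if self.n % 2 == 0:
            w[-1] = 1.0  # the Nyquist ordinate appears once
        return w

    def two_sided_total(self) -> float:
        """Total two-sided power; equals N * population variance (Parseval)."""
        return float(np.sum(self.two_sided_weights() * self.power))


@dataclass
class PoVResult:
    """Proportion-of-variance ratios for the fundamental and harmonic bands."""

    pov_f: float  # fundamental band only
    pov_h: float  # sum over the first n_harmonics bands
    per_harmonic: np.ndarray  # fraction captured by each band k = 1..n
    n_harmonics: int
    band_period_bounds: tuple[float, float]  # hours
    variance: float  # N-1 sample variance of the input


@dataclass
class CosinorFit:
    """Least-squares single-cosine fit X_t = M + a cos(w t) + b sin(w t)."""

    r_squared: float
    mesor: float
    amplitude: float
    acrophase: float  # radians, peak offset of the fitted cosine
    period_hours: float


def _values_dt(series, dt):
    if isinstance(series, EnmoSeries):
        return series.values, series.dt
    if dt is None:
        raise ValueError("dt required for a plain array")
    return np.asarray(series, dtype=float), float(dt)


def periodogram(series, dt: float | None = None) -> Spectrum:
    """Mean-removed periodogram on the one-sided Fourier grid.

    Raises :class:`DegenerateSeriesError` on constant input.
    """
    x, dt = _values_dt(series, dt)
    n = x.size
    if n < 2:
        raise DegenerateSeriesError("need at least 2 samples")
    xc = x - x.mean()
    if not np.any(xc):
        raise DegenerateSeriesError("degenerate series: zero variance")
    power = np.abs(np.fft.rfft(xc)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=dt)
    return Spectrum(freqs=freqs, power=power, dt=dt, n=n)


def band_power(
    spec: Spectrum,
    period_bounds_hours: tuple[float, float] = FUNDAMENTAL_BAND_HOURS,
    k: int = 1,
) -> float:
    """Fraction of total variance in the k-th harmonic band.

    The band covers Fourier frequencies f with
    ``k / (hi_hours * 3600) <= f <= k / (lo_hours * 3600)`` (edges
    inclusive); its two-sided mass is normalized by the two-sided total so
    that a band covering the whole axis returns exactly 1.

    A band lying beyond the Nyquist frequency raises; a band containing no
    Fourier frequency returns 0 with a warning (series too short to resolve
    the band).
    """
    lo_h, hi_h = period_bounds_hours
    if not (0 < lo_h < hi_h):
        raise ValueError("period bounds must satisfy 0 < lo < hi")
    k = int(k)
    if k < 1:
        raise ValueError("harmonic index must be >= 1")
    f_lo = k / (hi_h * 3600.0)
    f_hi = k / (lo_h * 3600.0)
    if f_lo > spec.nyquist:
        raise ValueError(
            f"band [{f_lo:.3g}, {f_hi:.3g}] Hz lies beyond the Nyquist "
            f"frequency {spec.nyquist:.3g} Hz"
        )
    # tiny relative slack keeps exact-edge Fourier frequencies inside
    eps = 1e-12
    mask = (spec.freqs >= f_lo * (1 - eps)) & (spec.freqs <= f_hi * (1 + eps))
    mask &= spec.freqs > 0
    if not np.any(mask):
        warnings.warn(
            f"harmonic band k={k} contains no Fourier frequency (series too "
            "short); returning 0",
            ActimetricsWarning,
            stacklevel=2,
        )
        return 0.0
    w = spec.two_sided_weights()
    return float(np.sum(w[mask] * spec.power[mask]) / spec.two_sided_total())


def pov(
    series,
    n_harmonics: int = 4,
    band_hours: tuple[float, float] = FUNDAMENTAL_BAND_HOURS,
    dt: float | None = None,
) -> PoVResult:
    """Proportion of variance around the circadian fundamental and harmonics.

    ``pov_f`` uses the fundamental band only (k = 1); ``pov_h`` sums the
    bands at k = 1..n_harmonics (default 4).  A recording shorter than about
    two days cannot resolve the fundamental band (no Fourier frequency falls
    inside it) and yields zeros with a warning.
    """
    x, dt = _values_dt(series, dt)
    spec = periodogram(x, dt=dt)
    per = np.array(
        [band_power(spec, band_hours, k) for k in range(1, int(n_harmonics) + 1)]
    )
    return PoVResult(
        pov_f=float(per[0]),
        pov_h=float(per.sum()),
        per_harmonic=per,
        n_harmonics=int(n_harmonics),
        band_period_bounds=band_hours,
        variance=float(np.var(x, ddof=1)),
    )


def cosinor(series, period_hours: float = 24.0, dt: float | None = None) -> CosinorFit:
    """Single-component cosinor fit by linear least squares.

    Fits ``X_t = M + a cos(2 pi t dt / T) + b sin(2 pi t dt / T)`` with the
    period T fixed (default 24 h); amplitude and acrophase are recovered from
    (a, b).  Returns the fit with its coefficient of determination R^2.
    """
    x, dt = _values_dt(series, dt)
    n = x.size
    if n < 3:
        raise DegenerateSeriesError("need at least 3 samples for a cosinor fit")
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst <= 0:
        raise DegenerateSeriesError("degenerate series: zero variance")
    w = 2.0 * np.pi * np.arange(n) * dt / (period_hours * 3600.0)
    design = np.column_stack([np.ones(n), np.cos(w), np.sin(w)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    mesor, a, b = (float(c) for c in coef)
    return CosinorFit(
        r_squared=r2,
        mesor=mesor,
        amplitude=float(np.hypot(a, b)),
        acrophase=float(np.arctan2(-b, a)),
        period_hours=float(period_hours),
    )


def cosinor_r2(series, period_hours: float = 24.0, dt: float | None = None) -> float:
    """Coefficient of determination of the fixed-period cosinor model."""
    return cosinor(series, period_hours=period_hours, dt=dt).r_squared
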