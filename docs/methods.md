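# Methods

This note documents the statistical procedures implemented in
`actimetrics`, the parameter defaults and the design choices made where the
methodology admits more than one reasonable implementation.

## Input model and preprocessing

The unit of analysis is an ENMO series: acceleration magnitude
√(ax² + ay² + az²) − 1 g, truncated at zero, sampled on a uniform grid
(typically every 5 s) with an absolute start time.  Truncation, rather than
absolute value, is used for the negative residuals left after gravity
subtraction: it matches ENMO's standard definition and the hard floor at
zero visible in real wrist data.

Timestamps are treated as naive local clock time; no daylight-saving
adjustment is made.  A recording's grid is validated with a 1% tolerance on
the inter-sample interval.

**Gap cleaning.**  Any calendar day touched by a sampling gap (inter-sample
interval > 1.5·dt, or < 0.5·dt indicating corrupted timestamps) is dropped
in full, together with days wholly absent inside a gap, and the surviving
days are spliced in chronological order.  Whole-day dropping is deliberate:
the clock-aligned statistics (IS, the day/night partition, daily profiles)
require every retained sample to keep its true time of day, which holds
after splicing whenever dt divides 86400 s (a warning is emitted otherwise).
The 1.5·dt threshold tolerates timestamp jitter without masking real
dropouts.  Cleaning is idempotent.

**Day/night partition.**  Samples are assigned by clock time to
day = [06:00, 23:00) and night = [23:00, 06:00) by default — the window of
low activity in group-average ENMO profiles.  Both boundaries are
configurable.  For the day/night DFA the per-day segments are concatenated
into one stream per partition; splice points are a known approximation
(detrending never crosses a segment boundary shorter than the largest
scale divided into it, but the profile does accumulate across splices).  A
`per_day` mode instead fits each contiguous run separately and averages the
exponents weighted by run length; on homogeneous data the two agree.

## Interdaily stability

IS pools all samples into 24 clock-hour bins across days (partial first and
last days contribute to whatever bins they cover) and takes the ratio of
the between-hour variance of bin means (divided by 24) to the population
variance (divided by N).  The variance decomposition bounds IS to [0, 1],
and the statistic is invariant to affine rescaling of the data.  Hourly
binning is retained even at 5-second sampling because IS is insensitive to
the bin width; empty bins or zero variance raise errors rather than
returning a silent value.

## Intradaily variability and the subsampling sweep

IV on a single sequence is the mean squared first difference (divided by
M − 1) over the population variance (divided by M).  At subsampling factor
Δ the series decomposes into Δ phase-shifted subsequences of length
M = ⌊N/Δ⌋ (phase j takes samples j, j+Δ, j+2Δ, …); IV is computed per phase
and averaged, so every sample participates regardless of Δ (at most Δ − 1
trailing samples are unused).  Phases with zero variance — near-constant
night stretches — are excluded with a warning instead of poisoning the
average; the degenerate-variance threshold is exact zero.

IV depends strongly on Δ: short-lag positive autocorrelation suppresses it
at high sampling rates and it rises toward its hourly-subsampling value as
Δ grows.  The sweep utility evaluates Δ = 1…720 (5 s to 60 min at 5-second
sampling) and marks the recommended 5-minute interval within the admissible
2–10 minute band — the range in which IV correlates with the other
statistics in the expected (negative) direction while still separating
groups.

## DFA scaling exponent

The profile is the cumulative sum of the mean-centered series (so Z_N = 0
identically).  For each scale S the profile is tiled from its head into
⌊N/S⌋ non-overlapping segments (trailing remainder discarded), an OLS line
is removed per segment, and the per-segment RMS residual uses the
population form (divide by S, not S − 2).  F(S) is the root of the mean of
squared per-segment residuals, and α is the slope of an unweighted OLS of
log₂F on log₂S, with the fit's R² reported as a quality diagnostic (R²
above 0.95 on clean fractal fixtures of length ≥ 2^16; real recordings in
this regime typically fit near 0.99).

The default grid is S = round(2^i), i = 4…8 step 0.25 — 17 scales from 16
to 256 samples, i.e. 1.333 to 21.333 minutes at 5-second sampling.
Fractional 2^i values are rounded to integers and deduplicated; the grid
minimum of 16 respects the rule of thumb that scales should exceed ~10
samples, and the per-segment residual needs S ≥ 4 to be meaningful for a
line fit.  Larger scales add cost without materially moving the exponent on
multi-day recordings.

Calibration on the reference noises: white noise α = 0.5, spectrally
synthesized 1/f noise α = 1.0, random walk α = 1.5, and integrating a
stationary series raises α by 1.  The Hurst exponent is recovered as H = α
(stationary, α ≤ 1) or H = α − 1 (nonstationary).

## Periodogram and proportion of variance

The periodogram of the mean-removed series, I(f) = |Σ(Xₜ − X̄)e^(−i2πft)|²/N,
is evaluated on the one-sided Fourier grid f = j/(N·dt); by Parseval the
two-sided sum (doubling interior frequencies) equals N times the population
variance, which the implementation maintains to 1e-9 relative.

PoV measures circadian strength as the fraction of variance in narrow bands
around the circadian fundamental: periods 23.5–24.5 h, i.e. |f| between
1/88200 and 1/84600 Hz, with band edges inclusive.  PoV⁽ᶠ⁾ uses the
fundamental band; PoV⁽ᴴ⁾ adds its integer multiples up to the 4th harmonic
(4 is the default because real activity waveforms are far from sinusoidal
and the first few harmonics carry most of the non-sinusoidal mass;
configurable).  Band mass is the sum of two-sided periodogram ordinates in
the band divided by the total two-sided sum.  This ratio-of-sums
normalization — rather than a Riemann integral over a continuous spectrum
with an N−1 variance denominator — makes "fraction of variance" exact,
keeps 0 ≤ PoV⁽ᶠ⁾ ≤ PoV⁽ᴴ⁾ ≤ 1 identically, and differs from the N−1 form
by less than 1/N relative.  No tapering or smoothing is applied: the band
itself already averages neighbouring frequencies.

A recording must span about two days before any Fourier frequency falls in
the fundamental band; shorter inputs yield zero with a warning.

The parametric comparator is the fixed-period cosinor model
X_t = M + a·cos(ωt) + b·sin(ωt) with ω = 2π/24 h, fitted by linear least
squares (amplitude and acrophase recovered from (a, b)); its R² is reported
alongside PoV.  On cohorts with graded circadian amplitude the cosinor R²
and PoV⁽ᶠ⁾ are nearly collinear; PoV⁽ᴴ⁾ separates from both when the
waveform is non-sinusoidal.

## Group comparison and correlations

Group contrasts use the two-sided Mann–Whitney U-test at the 5% level:
exact null distribution when the smaller group has ≤ 8 observations and
there are no ties, otherwise the normal approximation with continuity and
tie corrections (delegated to scipy).  Two-sided p doubles the smaller
tail, capped at 1.  No multiple-testing correction is applied; each
comparison is reported individually.  Cross-metric structure is summarised
with Pearson correlation matrices, and a sweep utility recomputes the
correlation of IV with IS, α and PoV⁽ᴴ⁾ at each subsampling factor.

## Synthetic data

`gen_circadian` builds X_t = max(0, baseline + Σ A_k cos(2πkt·dt/86400 + φ_k) + ε_t):
a harmonic circadian waveform (default peak 14:00, harmonic amplitudes
falling as 1 : 0.4 : 0.2 : 0.1) plus white or AR(1) Gaussian noise,
rectified at zero like real ENMO.  The AR(1) option reproduces the strong
short-lag autocorrelation of 5-second data that suppresses IV at small Δ.
`gen_noise` provides the calibration processes: i.i.d. Gaussian noise, 1/f
noise by spectral synthesis (deterministic 1/f amplitude profile with
seeded random phases — the target spectrum is exact and there are no filter
warm-up artefacts; requires a power-of-two length), and a random walk as
the cumulative sum of the white series from the same seed.  All generators
are bit-reproducible given their seed.

`gen_cohort` produces 40 recordings (default 7 days at 5-second sampling)
with the fundamental amplitude graded linearly from 0 to 0.08 g and, jointly,
AR(1) persistence rising (φ 0.2 → 0.6) and noise level falling (0.04 →
0.02 g) — so stronger rhythms are also smoother, the covariance pattern
real cohorts show; baselines keep values in the 0–0.2 g range typical of
wrist ENMO.  A ground-truth parameter table accompanies the recordings.

What the synthetic data does *not* emulate: non-wear episodes, posture
artefacts, movement bout structure, inter-day phase drift, or the heavy
right tail of real acceleration magnitudes.  Passing tests therefore
establish the estimators' correctness and calibration on known processes,
not the clinical properties of the statistics on patient data.

## Numerical choices and problem sizes

- Population (divide-by-N) variance in the IS and IV denominators and in
  the DFA residual; the PoV result also records the N−1 sample variance.
- Band edges and exact-edge Fourier frequencies are included with 1e-12
  relative slack to make edge membership robust to float rounding.
- DFA on constant input, zero-variance series, and empty clock-hour bins
  raise typed errors; per-recording evaluation converts failures to NaN
  with a warning, never to silent zeros.
- Monte-Carlo checks in the test suite use 2^16–2^17-sample series with
  20–50 seeds for the scaling-exponent calibrations, chosen so the sample
  mean's spread sits well inside the asserted bands while the whole suite
  runs in well under a minute; the cohort fixtures use 40 recordings of 7
  days at 5-second sampling.

## Known limitations

- Day/night DFA on concatenated streams treats splices as contiguous;
  per-day mode is available where that approximation matters.
- IS requires at least one sample in every clock hour; very short or
  heavily gapped recordings are rejected rather than extrapolated.
- PoV's band discretization means very short recordings resolve the
  fundamental band with only a handful of Fourier frequencies; several days
  of data are needed for a stable estimate.
- The Mann–Whitney exact path is limited to small untied samples; ties in
  small samples fall back to the corrected normal approximation.
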