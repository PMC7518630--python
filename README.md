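# actimetrics

Nonparametric circadian summary statistics for high-frequency wrist
accelerometry.

Modern actigraphs record acceleration every few seconds for days or weeks.
For populations with dysregulated rest–activity rhythms — people with
advanced dementia are the motivating case — parametric rhythm models fit
poorly, and summary statistics designed for hourly actigraphy counts need
care when applied to 5-second ENMO (Euclidean-norm-minus-one) data.  This
package computes four nonparametric per-recording statistics, tuned for
high-frequency sampling, plus the preprocessing, synthetic validation data
and cohort reporting around them:

- **Interdaily stability (IS)** — strength of the 24-hour rhythm:
  `IS = [Σₛ (X̄ₛ − X̄)² / 24] / [Σₜ (Xₜ − X̄)² / N]`, with `X̄ₛ` the mean over
  all samples in clock hour *s*.  IS ∈ [0, 1]; 1 means a perfectly repeating
  daily pattern.
- **Intradaily variability (IV)** — fragmentation of activity:
  mean squared consecutive difference over variance, computed on every one
  of the Δ phase-shifted subsamples of the series and averaged, so no data
  is discarded whatever the subsampling factor Δ.  IV ≈ 2 for white noise.
  The recommended subsampling interval is 5 minutes (admissible 2–10 min).
- **DFA scaling exponent (α)** — long-range correlation via detrended
  fluctuation analysis with linear detrending on scales S = round(2^i),
  i = 4…8 step 0.25 (1.33–21.33 min at 5 s sampling); α is the slope of
  log₂F(S) on log₂S.  White noise gives α = 0.5, 1/f noise α = 1, a random
  walk α = 1.5.  Separate day/night exponents use the 06:00–23:00 /
  23:00–06:00 clock partition.
- **Proportion of variance (PoV)** — a spectral measure of circadian
  strength: the fraction of total variance the periodogram
  `I(f) = |Σₜ (Xₜ − X̄) e^(−i2πft)|² / N` carries in the period band
  23.5–24.5 h (PoV⁽ᶠ⁾) and in that band plus its 2nd–4th harmonics
  (PoV⁽ᴴ⁾).  Unlike the cosinor fit (also provided, as comparator), PoV
  makes no waveform assumption.

Synthetic generators (`gen_circadian`, `gen_noise`, `gen_cohort`) provide
ENMO-like recordings and reference noises with analytically known values of
every statistic, so the whole suite is testable without clinical data.

## Worked example

```python
import actimetrics as am

spec = am.CircadianSpec(days=7, dt=5.0, seed=42, noise_kind="ar1", ar1_phi=0.4)
series = am.gen_circadian(spec)          # 7 days of 5-second synthetic ENMO
row = am.evaluate_recording(series, recording_id="demo", iv_delta=60)
for k in ("is", "iv", "alpha", "alpha_day", "alpha_night",
          "pov_f", "pov_h", "cosinor_r2"):
    print(f"{k:12s} {row[k]:.4f}")
```

prints

```
is           0.6488
iv           0.6894
alpha        0.5738
alpha_day    0.5749
alpha_night  0.5695
pov_f        0.5224
pov_h        0.6562
cosinor_r2   0.5224
```

The recording has a clear but noisy daily rhythm: IS well above 0 but below
1; IV below 2 (consecutive 5-minute epochs are smoother than white noise);
α between 0.5 and 1 (stationary, positively correlated); the fundamental
band alone captures 52% of the variance and the harmonics raise that to
66%, reflecting the non-sinusoidal waveform; the cosinor R² nearly equals
PoV⁽ᶠ⁾, as it should for a fixed 24-h cosine.

The same pipeline runs from the shell:

```bash
actimetrics simulate --kind circadian --days 7 --dt 5 --seed 42 --out rec.csv
actimetrics compute --input rec.csv --iv-delta 5min --out metrics.csv
actimetrics sweep-iv --input rec.csv --min 1 --max 720 --out sweep.csv
actimetrics dfa --input rec.csv --split daynight
actimetrics pov --input rec.csv --with-cosinor
actimetrics report --metrics metrics.csv --groups groups.csv --out report.json
```

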