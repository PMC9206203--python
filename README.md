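# nighthrv

Nightly heart-rate-variability (HRV) trend analysis from low-rate wrist
photoplethysmography (PPG), built for longitudinal cohort studies — the
motivating setting is pregnancy, where nightly HRV drifts slowly across the
second and third trimesters and rebounds postpartum.

## The problem

Wrist wearables record PPG at low sampling rates (20 Hz here) for months at
a time. Turning that into a credible statement like "SDNN falls by x ms per
gestational day" requires a chain of steps, each of which can silently bias
the result:

1. **Signal quality screening.** Daytime and motion-corrupted segments are
   useless; a classifier over five waveform features (skewness, kurtosis,
   approximate entropy, Shannon entropy, spectral entropy) separates clean
   pulse signals from corrupted ones.
2. **Beat detection.** A zero-phase 0.7–3.5 Hz Butterworth bandpass removes
   drift and high-frequency noise; an adaptive moving-average threshold
   finds one beat per pulse; parabolic sub-sample refinement breaks the
   50 ms quantization a 20 Hz grid would otherwise impose on interbeat
   intervals (IBIs).
3. **IBI cleaning.** IBIs deviating more than 30% from their 5-minute
   segment mean are rejected (masked, never deleted).
4. **HRV metrics.** Per 5-minute window with at least 150 accepted beats:
   HR, AVNN, SDNN, RMSSD, and Welch-based LF/HF band powers of the
   spline-interpolated tachogram — each also in a normalized variant
   (IBIs scaled to mean 100) that removes mean-heart-rate dependence.
5. **Night aggregation.** Only windows starting between 00:00 and 06:00
   count; each subject-night collapses to the minimum-heart-rate window
   (the most reliably at-rest stretch); nights are labelled trimester 2
   (gestational weeks 16–28), trimester 3 (29–40) or postpartum (first 12
   weeks), and a reliability table accounts for every possible night.
6. **Trend models.** Per period and parameter, a hierarchical linear mixed
   model `value ~ day_in_period + age + bmi + education` with per-subject
   random intercepts and slopes (REML, Wald tests). Preterm deliveries
   (before week 37) are excluded from third-trimester fits.

A synthetic cohort generator produces PPG with fully known ground truth —
true beat times, quality labels, per-subject random effects and population
slopes — so every stage of the chain is testable against the truth.

## Worked example

```python
from nighthrv import IbiProfile, simulate_ibi_series
from nighthrv.core import IbiSeries
from nighthrv.hrv import window_hrv

profile = IbiProfile(mean_ibi_ms=920, lf_amp_ms=40, hf_amp_ms=30,
                     jitter_sd_ms=5, duration_s=720)
beats, _ = simulate_ibi_series(profile, seed=3)
windows = window_hrv(IbiSeries.from_beat_times(beats))
w = windows.iloc[0]
print(f"HR {w.HR:.1f} bpm, SDNN {w.SDNN:.1f} ms "
      f"(analytic target {profile.asymptotic_sdnn_ms:.1f} ms)")
```

Output:

```
HR 65.3 bpm, SDNN 35.9 ms (analytic target 35.7 ms)
```

And the trend model on a panel with a known slope
(`python examples/05_night_trends.py`):

```
true SDNN slope -0.08 ms/day; fitted -0.0783 (95% CI [-0.1507, -0.0059], p=0.034)
random effects: intercept+slope over 24 subjects and 720 nights
period comparison: postpartum sits 10.1 ms above trimester 2 (true offset 10.0, p=4e-132)
weekly profile: week 16 mean 59.3 ms -> week 20 mean 56.6 ms (-2.7 ms across the period)
```

The `examples/` directory has one short script per capability: cohort
simulation, quality screening, beat detection, HRV windows, and trend
models. Each prints computed numbers against known truth.

## Command line

A thin CLI wraps the library for batch use:

```bash
nighthrv simulate --n-subjects 6 --seed 1 --out cohort/   # synthetic cohort
nighthrv quality-train --manifest cohort/manifest.json --out model.joblib
nighthrv process --config config.json                     # full pipeline
nighthrv trends --cohort out/cohort.csv --parameter SDNN --period trimester2
nighthrv report --counts night_counts.json                # reliability table
```

`process` writes five artifacts (windows, cohort, trends, reliability,
exclusions) plus a manifest with a config hash; a rerun with the same
config and seed is byte-identical.

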