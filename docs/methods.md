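# Methods note

This note records the generative model, the analysis chain, every default
parameter with its rationale, and the numerical choices that are the
package's own rather than forced by the problem.

## 1. Synthetic generator

### IBI process

A segment's interbeat intervals follow

```
IBI(t_k) = mean_ibi + lf_amp * sin(2*pi*0.10*t_k)
                    + hf_amp * sin(2*pi*0.25*t_k) + e_k,
e_k ~ Normal(0, jitter_sd^2)
```

with beat times accumulated sequentially (`t_{k+1} = t_k + IBI(t_k)/1000`).
0.10 Hz sits mid-LF (0.04–0.15 Hz) and 0.25 Hz mid-HF (0.15–0.40 Hz), so the
two amplitudes place variance in known spectral bands. A sinusoid of
amplitude `a` has variance `a^2/2`, so the jitter-free SDNN is
`sqrt(lf_amp^2 + hf_amp^2)/sqrt(2)` (`IbiProfile.asymptotic_sdnn_ms`), which
is what window-level SDNN estimates are tested against. Profiles whose
modulation would drive an IBI below 1 ms are rejected rather than clipped —
they indicate a mis-specified design, and clipping would silently change the
target SDNN.

### Waveform rendering

Each beat is a Gaussian pulse centred on the (continuous) beat time,
`sigma = pulse_width_s / 2` with `pulse_width_s = 0.2 s` — wide enough that
a 20 Hz grid samples every pulse several times, narrow enough that adjacent
pulses at 180 bpm do not merge. Because pulse centres are continuous, the
rendered signal carries sub-sample timing information that parabolic
refinement can recover.

### Corruption modes

`gaussian_noise` (additive noise at `severity` times the signal SD),
`motion_burst` (a large low-frequency excursion plus noise over a random
stretch) and `flatline` (a dead-sensor stretch). These are the failure modes
screening must catch: broadband noise, motion artifact, and dropout.

### Cohort designs

`SimulationDesign` defaults describe the study protocol the package targets:
58 subjects, 12-minute segments every 2 hours at 20 Hz restricted to
00:00–06:00, gestational weeks 16–40 plus 12 postpartum weeks, ~20% of
segments corrupted, ~12% preterm deliveries, and covariates (age
31.9 ± 4.9 y, BMI 26.0 ± 6.0, education in three levels at 41/31/28%)
matching a plausible pregnancy cohort. Per-subject and per-period true
slopes are drawn around `PeriodTruth` population values, giving every
segment a known target AVNN/SDNN.

Tests and the acceptance script instantiate explicit scaled-down designs
(few subjects, few weeks); full-scale cohorts are generator defaults, not
test fixtures. Realism limits: the waveform has no dicrotic notch, no
respiratory amplitude modulation, and corruption severities are stylized;
the generator is built for *known truth*, not morphological fidelity.

### Night-level panels

`simulate_night_panel` draws subject-night values directly from the mixed
model (random intercept + random slope + residual), skipping PPG rendering.
Calibration studies need hundreds of replicate cohorts; rendering 20 Hz PPG
for each adds hours of compute and no information about the estimator under
test. The calibration panel size — 24 subjects × 30 nights — is the
package's own choice: large enough that the random-slope variance is
identified in most replicates, small enough that 300 replicate fits run in
roughly two minutes on one CPU.

## 2. Quality screening

Features per 5-minute subsegment, computed on the z-scored signal so they
are amplitude-invariant: skewness, Pearson kurtosis (Gaussian reference 3),
approximate entropy (m = 2, r = 0.2·SD, Chebyshev distance), Shannon entropy
of a 32-bin amplitude histogram, and Welch spectral entropy normalized to
[0, 1] by log(number of frequency bins). Approximate entropy is O(n²); it is
computed on the first 60 s (1200 samples) of each subsegment, which
preserves its discrimination while keeping screening ~50× cheaper. A
recording is reliable iff **all** complete subsegments classify reliable —
one corrupted stretch invalidates the night window containing it.
Degenerate segments (zero peak-to-peak range) are rejected before
feature extraction: several features are undefined on them, and a flat
segment needs no classifier.

The classifier is an RBF-kernel SVM (C = 1, scaled gamma) behind a
standardizing pipeline, persisted with joblib plus a JSON sidecar of scaler
constants. Training requires ≥ 10 labelled segments spanning both classes.

## 3. Beat detection and IBI cleaning

- **Bandpass 0.7–3.5 Hz** brackets 42–210 bpm. Applied forward-backward
  (zero phase) so peak positions are unbiased. The filter is **order 3**: an
  order-2 Butterworth applied twice attenuates a 1 Hz pulse by 7.5%,
  violating the requirement that in-band pulses survive within 5%; order 3
  passes 1 Hz at two-pass gain 0.977 while attenuating 0.1 Hz drift by
  ~112 dB (requirement: ≥ 20 dB).
- **Adaptive threshold:** a 0.75 s moving average tracks the baseline;
  regions above the moving average plus an offset yield one candidate beat
  each (region argmax). The offset is chosen from a grid of 5–300% of the
  signal RMS; among offsets whose implied rate is physiological
  (40–180 bpm), the one minimizing IBI standard deviation wins — spurious
  and missed beats both inflate IBI dispersion.
- **Parabolic refinement:** a 3-point parabola through each peak gives
  sub-sample positions (shift clipped to ±0.5 samples). At 20 Hz this is
  what makes RMSSD usable: raw argmax positions quantize IBIs to 50 ms.
- **30% rule:** within each 5-minute stretch, IBIs outside ±30% of the
  stretch mean (computed once, over raw IBIs) are masked. Mask-only, single
  pass — hence idempotent, and RMSSD later uses only adjacent accepted
  pairs, never bridging across a rejected IBI.

## 4. HRV metrics

Per half-open 5-minute window with ≥ 150 accepted beats (at plausible
nightly heart rates a much lower count signals detection failure, not
physiology): AVNN, SDNN (ddof = 1), RMSSD over adjacent accepted pairs,
HR = 60000/AVNN. Normalized variants recompute each metric after scaling
IBIs to `100 * IBI / mean(IBI)`; nSDNN is then the coefficient of variation
in percent. Frequency domain: cubic-spline interpolation of the accepted
tachogram to 4 Hz (Nyquist 2 Hz comfortably above the 0.4 Hz HF edge),
Welch with 120 s Hann windows at 50% overlap (two full cycles of the lowest
LF frequency per window), trapezoidal band integration over LF [0.04, 0.15)
and HF [0.15, 0.40). A Lomb–Scargle alternative avoids interpolation
entirely and is used as a cross-check. Windows spanning under 240 s of
beats raise rather than return unstable estimates.

## 5. Night aggregation

Night = windows starting in [00:00, 06:00) local time. Default nightly
summary is the **minimum-HR window**, one coherent resting snapshot
(parameter-wise means across a night mix physiological states and dilute
within-night artifacts); `mean` mode is available. Period boundaries in
gestational days: trimester 2 = [112, 203), trimester 3 = [203, 287),
postpartum < 84 days after delivery; everything else (including the stretch
between week 40 and an overdue delivery) is excluded. Preterm = delivery
before gestational day 259 (week 37). The reliability table reports, per
period, reliable and possible nights and the exact percentage (2 decimals),
plus an integer total row.

## 6. Trend models

`value ~ day_in_period + age + bmi + education` with per-subject random
intercept and random slope on `day_in_period`, fit by REML (statsmodels
MixedLM; lbfgs, then bfgs, then cg), Wald z tests. The model falls back to
a random intercept only on *genuine* failure — an exception, a
non-converged optimizer, or non-finite coefficients/standard errors —
never on a mere convergence warning, which would shrink the slope's
standard error and destroy CI coverage (this exact failure was observed at
0.80 coverage with an eager fallback and is pinned by the calibration
test). Period comparisons add a binary indicator for the second period with
time re-anchored to each period's own start; weekly profiles report
mean ± 1.96·SE. Preterm subjects are excluded from trimester-3 fits
automatically. Fits require ≥ 5 subjects with ≥ 3 nights each.

## 7. Calibration and problem sizes

The acceptance calibration runs 100 slope-recovery replicates (truth
−0.08 ms/day, between-subject SD 12 ms, slope SD 0.05, residual SD 8 ms)
and 200 null replicates at 24 subjects × 30 nights. Observed: CI coverage
0.93–0.96 across seeds (threshold ≥ 0.90), null rejection 0.035–0.075
(required within [0.02, 0.10]). These sizes are deliberate scale-downs for
a single-CPU budget; they are the package's own choice and the thresholds
are calibration properties of the estimator, not of any particular dataset.

## 8. Known limitations

- The waveform model omits dicrotic notches, respiratory modulation and
  baseline wander within clean segments; the quality classifier is
  therefore only as hard-tested as the corruption modes are realistic.
- Approximate entropy on a 60 s prefix assumes stationarity within the
  subsegment.
- The mixed model assumes Gaussian random effects and residuals; the Wald
  tests are asymptotic and the calibration panel documents their finite-
  sample behaviour only at the sizes stated above.
- Local clock time is taken at face value (no time-zone or DST handling).
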