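"""Synthetic wearable cohort with analytically known heart-rate variability.

The study's raw recordings are not public, so every downstream stage is
exercised against signals generated here: interbeat-interval (IBI) sequences
with sinusoidal low-frequency (0.10 Hz) and high-frequency (0.25 Hz)
modulation whose time- and frequency-domain HRV metrics have closed forms,
rendered as 20 Hz pulse-shaped PPG, optionally corrupted to provide labelled
"unreliable" segments, and assembled into longitudinal pregnancy/postpartum
cohorts with known per-subject trend parameters.

Closed forms used by the tests: for a jitter-free profile the IBI variance is
``lf_amp**2/2 + hf_amp**2/2`` (RMS of a sinusoid is amplitude/sqrt(2)), so
SDNN -> sqrt(lf_amp**2 + hf_amp**2)/sqrt(2); AVNN -> mean_ibi_ms; with
``lf_amp == hf_amp == a`` the asymptotic SDNN is exactly ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .core import PpgRecording

LF_DRIVER_HZ = 0.10   # centre of the 0.04-0.15 Hz band
HF_DRIVER_HZ = 0.25   # centre of the 0.15-0.40 Hz band

CORRUPTION_MODES = ("gaussian_noise", "motion_burst", "flatline")


@dataclass
class IbiProfile:
    """Parameters of one synthetic beat process.

    mean_ibi_ms : baseline interbeat interval (300-2000 ms).
    lf_amp_ms / hf_amp_ms : amplitudes of the 0.10 / 0.25 Hz modulations.
    jitter_sd_ms : white beat-to-beat noise SD.
    duration_s : length of the generated series.
    """

    mean_ibi_ms: float
    lf_amp_ms: float = 0.0
    hf_amp_ms: float = 0.0
    jitter_sd_ms: float = 0.0
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        if not (300.0 <= self.mean_ibi_ms <= 2000.0):
            raise ValueError("mean_ibi_ms must lie in [300, 2000]")
        if min(self.lf_amp_ms, self.hf_amp_ms, self.jitter_sd_ms) < 0:
            raise ValueError("amplitudes and jitter must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def asymptotic_sdnn_ms(self) -> float:
        """SDNN the process converges to as duration grows."""
        return math.sqrt(self.lf_amp_ms ** 2 / 2 + self.hf_amp_ms ** 2 / 2
                         + self.jitter_sd_ms ** 2)


def simulate_ibi_series(profile: IbiProfile, seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Generate beat times (s) and IBIs (ms) for one profile.

    IBI(t_k) = mean + lf_amp*sin(2*pi*0.10*t_k) + hf_amp*sin(2*pi*0.25*t_k)
    + Normal(0, jitter_sd**2); beat times are the cumulative sums. The same
    (profile, seed) pair always yields the identical sequence.
    """
    rng = np.random.default_rng(seed)
    beat_times = [0.0]
    ibis = []
    t = 0.0
    while t < profile.duration_s:
        ibi = (profile.mean_ibi_ms
               + profile.lf_amp_ms * math.sin(2 * math.pi * LF_DRIVER_HZ * t)
               + profile.hf_amp_ms * math.sin(2 * math.pi * HF_DRIVER_HZ * t))
        if profile.jitter_sd_ms > 0:
            ibi += rng.normal(0.0, profile.jitter_sd_ms)
        if ibi < 1.0:   # an IBI under 1 ms is non-physical: degenerate profile
            raise ValueError("profile implies a non-positive IBI")
        t += ibi / 1000.0
        beat_times.append(t)
        ibis.append(ibi)
    return np.asarray(beat_times), np.asarray(ibis)


def render_ppg(beats: np.ndarray, fs: float = 20.0, *,
               pulse_width_s: float = 0.2, amplitude: float = 1.0,
               duration_s: float | None = None, subject_id: str = "synthetic",
               start_time: datetime | None = None) -> PpgRecording:
    """Render beat times as a pulse train sampled at ``fs``.

    Each beat contributes one Gaussian pulse (sigma = pulse_width_s / 2)
    centred on its beat time, so the dominant local maxima of the rendered
    signal fall within one sample of the true beats.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.size == 0:
        raise ValueError("at least one beat time is required")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if beats.size > 1 and np.any(np.diff(beats) <= 0):
        raise ValueError("beat times must be strictly increasing")
    sigma = pulse_width_s / 2.0
    if duration_s is None:
        duration_s = float(beats[-1]) + 4 * sigma
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    signal = np.zeros(n)
    half = 5 * sigma
    for b in beats:
        lo = max(0, int((b - half) * fs))
        hi = min(n, int((b + half) * fs) + 1)
        if lo < hi:
            signal[lo:hi] += amplitude * np.exp(
                -0.5 * ((t[lo:hi] - b) / sigma) ** 2)
    if start_time is None:
        start_time = datetime(2000, 1, 1)
    return PpgRecording(subject_id=subject_id, start_time=start_time,
                        fs=fs, samples=signal, quality_label="reliable")


def corrupt_segment(rec: PpgRecording, mode: str, severity: float,
                    seed: int) -> PpgRecording:
    """Return a corrupted, "unreliable"-labelled copy of a recording.

    Modes: ``gaussian_noise`` adds white noise of SD ``severity`` (a.u.);
    ``motion_burst`` superimposes a random-walk artifact of SD ``severity``
    over a random sub-interval; ``flatline`` replaces the signal by its mean.
    """
    if severity <= 0:
        raise ValueError("severity must be positive")
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    rng = np.random.default_rng(seed)
    x = rec.samples.copy()
    n = x.size
    if mode == "gaussian_noise":
        x = x + rng.normal(0.0, severity, size=n)
    elif mode == "motion_burst":
        frac = rng.uniform(0.3, 0.7)
        length = max(int(frac * n), 2)
        start = rng.integers(0, n - length + 1)
        walk = np.cumsum(rng.normal(size=length))
        walk = walk - walk.mean()
        sd = walk.std()
        if sd > 0:
            walk *= severity / sd
        x[start:start + length] += walk
    else:  # flatline
        x = np.full(n, x.mean())
    return rec.with_samples(x, quality_label="unreliable")


# ---------------------------------------------------------------------------
# Cohort-level simulation


@dataclass
class PeriodTruth:
    """True mixed-model parameters for one observation period.

    Intercepts/slopes drive the baseline interbeat interval (AVNN, ms) and
    overall variability (SDNN, ms); between-subject SDs generate random
    intercepts and slopes; ``night_resid_sd`` is night-level noise used by
    the night-panel generator.
    """

    avnn_intercept: float
    avnn_slope: float            # ms per day
    sdnn_intercept: float
    sdnn_slope: float            # ms per day
    avnn_subject_sd: float = 60.0
    avnn_slope_sd: float = 0.2
    sdnn_subject_sd: float = 12.0
    sdnn_slope_sd: float = 0.03
    night_resid_sd: float = 8.0


def default_period_truths() -> dict[str, PeriodTruth]:
    """Trend magnitudes of the order reported for pregnancy cohorts:
    IBI shortens through the second trimester, recovers in the third,
    and is higher with a flat trend postpartum."""
    return {
        "trimester2": PeriodTruth(920.0, -0.585, 60.0, -0.082),
        "trimester3": PeriodTruth(850.0, 0.345, 52.0, 0.084),
        "postpartum": PeriodTruth(1000.0, 0.130, 65.0, 0.001),
    }


@dataclass
class SimulationDesign:
    """Study design for a synthetic longitudinal cohort.

    Defaults mirror the wearable protocol: 12-minute segments every 2 hours
    at 20 Hz from gestational week 16 to week 40 plus 12 postpartum weeks,
    with covariates drawn to match the cohort's background table (age
    31.9 +/- 4.9 y, BMI 25.98 +/- 5.96, education 41/31/28% across high
    school / college / university) and ~12% preterm deliveries.
    """

    n_subjects: int = 58
    period_truths: dict[str, PeriodTruth] = field(
        default_factory=default_period_truths)
    artifact_fraction: float = 0.2
    fs: float = 20.0
    segment_minutes: float = 12.0
    segment_gap_hours: float = 2.0
    night_only: bool = True
    ga_start_week: int = 16
    ga_end_week: int = 40
    postpartum_weeks: int = 12
    day_step: int = 1            # use every k-th calendar day
    jitter_sd_ms: float = 5.0
    pulse_width_s: float = 0.2
    preterm_fraction: float = 7.0 / 58.0
    age_mean: float = 31.9
    age_sd: float = 4.9
    bmi_mean: float = 25.98
    bmi_sd: float = 5.96
    education_probs: tuple[float, float, float] = (0.41, 0.31, 0.28)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")
        for p, t in self.period_truths.items():
            if not (np.isfinite(t.avnn_slope) and np.isfinite(t.sdnn_slope)):
                raise ValueError(f"non-finite slope for period {p!r}")
        required = {"trimester2", "trimester3", "postpartum"}
        if not required <= set(self.period_truths):
            raise ValueError("period_truths must define "
                             "trimester2/trimester3/postpartum")
        if self.ga_start_week > self.ga_end_week:
            raise ValueError("inconsistent gestational week range")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    subjects: pd.DataFrame       # covariates + per-period random effects
    segments: pd.DataFrame       # one row per generated segment
    beat_times: dict[str, np.ndarray]  # segment_id -> true beat times (s)


def _draw_covariates(design: SimulationDesign, rng: np.random.Generator
                     ) -> pd.DataFrame:
    n = design.n_subjects
    age = rng.normal(design.age_mean, design.age_sd, n).clip(18, 50)
    bmi = rng.normal(design.bmi_mean, design.bmi_sd, n).clip(16, 50)
    edu = rng.choice([0, 1, 2], size=n, p=design.education_probs)
    n_pre = int(round(design.preterm_fraction * n))
    preterm = np.zeros(n, dtype=bool)
    preterm[rng.choice(n, size=n_pre, replace=False)] = True
    # term deliveries centred on 280 gestational days; preterm before day 259
    delivery = np.where(
        preterm,
        rng.uniform(230, 258, n),
        rng.normal(281, 7, n).clip(260, 295),
    )
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 1),
        "education": edu,
        "delivery_ga_days": np.round(delivery).astype(int),
    })


def _period_of_ga(ga_days: int, delivery_ga_days: int) -> tuple[str, int]:
    """Period label and day-in-period for a pregnancy day (GA in days)."""
    if 112 <= ga_days < 203:
        return "trimester2", ga_days - 112
    if 203 <= ga_days < 287:
        return "trimester3", ga_days - 203
    return "excluded", 0


def simulate_cohort(design: SimulationDesign
                    ) -> tuple[list[PpgRecording], pd.DataFrame, GroundTruth]:
    """Generate a full labelled cohort of PPG segments.

    Returns the recordings, the covariate table, and the ground truth
    (per-subject random effects, per-segment quality labels and true beat
    times). All randomness flows from ``design.seed`` through a
    ``SeedSequence`` split: one child stream per subject plus one for the
    cohort-level draws, so outputs are bit-reproducible.
    """
    root = np.random.SeedSequence(design.seed)
    cohort_ss, *subject_ss = root.spawn(design.n_subjects + 1)
    rng = np.random.default_rng(cohort_ss)
    cov = _draw_covariates(design, rng)

    truths = design.period_truths
    effects = {}
    for period, t in truths.items():
        effects[period] = {
            "avnn_u0": rng.normal(0, t.avnn_subject_sd, design.n_subjects),
            "avnn_u1": rng.normal(0, t.avnn_slope_sd, design.n_subjects),
            "sdnn_u0": rng.normal(0, t.sdnn_subject_sd, design.n_subjects),
            "sdnn_u1": rng.normal(0, t.sdnn_slope_sd, design.n_subjects),
        }
    subj_rows = cov.copy()
    for period, eff in effects.items():
        for k, v in eff.items():
            subj_rows[f"{period}_{k}"] = v

    enrol_date = datetime(2020, 1, 6)   # arbitrary anchor; GA 112 d that day
    seg_len = timedelta(minutes=design.segment_minutes)
    hours = [h for h in np.arange(0, 24, design.segment_gap_hours)
             if (h < 6 or not design.night_only)]

    recordings: list[PpgRecording] = []
    seg_rows = []
    beat_map: dict[str, np.ndarray] = {}
    ga_start_d = design.ga_start_week * 7
    ga_end_d = design.ga_end_week * 7 + 6

    for i in range(design.n_subjects):
        srng = np.random.default_rng(subject_ss[i])
        sid = cov.subject_id[i]
        delivery = int(cov.delivery_ga_days[i])
        # pregnancy days then postpartum days, thinned by day_step
        preg_days = range(ga_start_d, min(ga_end_d + 1, delivery),
                          design.day_step)
        pp_days = range(0, design.postpartum_weeks * 7, design.day_step)
        calendar = ([("pregnant", d) for d in preg_days]
                    + [("postpartum", d) for d in pp_days])
        for phase, d in calendar:
            if phase == "pregnant":
                period, day_in = _period_of_ga(d, delivery)
                date = enrol_date + timedelta(days=d - ga_start_d)
            else:
                period, day_in = "postpartum", d
                date = enrol_date + timedelta(days=delivery - ga_start_d + d)
            if period in truths:
                t = truths[period]
                eff = effects[period]
                avnn = (t.avnn_intercept + eff["avnn_u0"][i]
                        + (t.avnn_slope + eff["avnn_u1"][i]) * day_in)
                sdnn = (t.sdnn_intercept + eff["sdnn_u0"][i]
                        + (t.sdnn_slope + eff["sdnn_u1"][i]) * day_in)
            else:
                avnn, sdnn = 950.0, 55.0
            avnn = float(np.clip(avnn, 450, 1600))
            sdnn = float(np.clip(sdnn, 5, avnn / 4))
            for h in hours:
                seg_id = f"{sid}_{date:%Y%m%d}_{int(h * 60):04d}"
                profile = IbiProfile(
                    mean_ibi_ms=avnn,
                    # equal-amplitude LF/HF drivers: var = 2*(a^2/2) = a^2,
                    # so the asymptotic SDNN equals the target directly
                    lf_amp_ms=sdnn,
                    hf_amp_ms=sdnn,
                    jitter_sd_ms=design.jitter_sd_ms,
                    duration_s=design.segment_minutes * 60.0,
                )
                beat_seed = int(srng.integers(0, 2 ** 31 - 1))
                beats, _ = simulate_ibi_series(profile, beat_seed)
                start = date + timedelta(hours=float(h))
                rec = render_ppg(beats, design.fs,
                                 pulse_width_s=design.pulse_width_s,
                                 duration_s=design.segment_minutes * 60.0,
                                 subject_id=sid, start_time=start)
                label = "reliable"
                if srng.uniform() < design.artifact_fraction:
                    mode = CORRUPTION_MODES[int(srng.integers(0, 3))]
                    sev = 5.0 if mode == "gaussian_noise" else 8.0
                    rec = corrupt_segment(rec, mode, sev,
                                          int(srng.integers(0, 2 ** 31 - 1)))
                    label = "unreliable"
                recordings.append(rec)
                beat_map[seg_id] = beats
                seg_rows.append({
                    "segment_id": seg_id, "subject_id": sid,
                    "start_time": start, "period": period,
                    "day_in_period": day_in, "is_night": h < 6,
                    "quality_label": label,
                    "true_avnn_ms": avnn, "true_sdnn_ms": sdnn,
                })

    segments = pd.DataFrame(seg_rows)
    gt = GroundTruth(subjects=subj_rows, segments=segments,
                     beat_times=beat_map)
    covariates = cov.drop(columns=["delivery_ga_days"]).assign(
        delivery_ga_days=cov.delivery_ga_days,
        preterm=cov.delivery_ga_days < 259,
        enrolment_date=enrol_date,
        ga_at_enrolment_days=ga_start_d,
    )
    return recordings, covariates, gt


def simulate_night_panel(*, n_subjects: int, n_nights: int,
                         intercept: float, slope: float,
                         subject_sd: float, slope_sd: float,
                         resid_sd: float, parameter: str = "SDNN",
                         period: str = "trimester2",
                         age_coef: float = 0.0, bmi_coef: float = 0.0,
                         education_coef: float = 0.0,
                         period_offset: float = 0.0,
                         second_period: str | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Generate a night-level panel directly from the mixed-model process.

    One row per subject-night: value = (intercept + u0_i) +
    (slope + u1_i) * day + covariate terms + Normal(0, resid_sd). Used for
    trend-recovery and calibration studies where rendering raw PPG for every
    replicate would add nothing. With ``second_period`` set, each subject
    contributes both periods and ``period_offset`` shifts the second.
    """
    rng = np.random.default_rng(seed)
    age = rng.normal(31.9, 4.9, n_subjects).clip(18, 50)
    bmi = rng.normal(25.98, 5.96, n_subjects).clip(16, 50)
    edu = rng.choice([0, 1, 2], size=n_subjects, p=(0.41, 0.31, 0.28))
    u0 = rng.normal(0, subject_sd, n_subjects)
    u1 = rng.normal(0, slope_sd, n_subjects)
    periods = [period] if second_period is None else [period, second_period]
    rows = []
    for i in range(n_subjects):
        for p_idx, per in enumerate(periods):
            days = np.arange(n_nights)
            vals = ((intercept + u0[i]) + (slope + u1[i]) * days
                    + age_coef * age[i] + bmi_coef * bmi[i]
                    + education_coef * edu[i]
                    + period_offset * p_idx
                    + rng.normal(0, resid_sd, n_nights))
            for d, v in zip(days, vals):
                rows.append({"subject_id": f"S{i:03d}", "period": per,
                             "day_in_period": int(d), "age": age[i],
                             "bmi": bmi[i], "education": int(edu[i]),
                             parameter: v})
    return pd.DataFrame(rows)
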