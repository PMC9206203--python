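"""Beat detection and interbeat-interval cleaning for low-rate wrist PPG.

The chain is: zero-phase Butterworth bandpass (0.7-3.5 Hz, the human heart
rate range), adaptive moving-average peak detection, sub-sample parabolic
refinement (at 20 Hz a raw argmax quantizes IBIs to 50 ms, which would
swamp RMSSD), and a 30% deviation-from-segment-mean rejection rule applied
over 5-minute segments.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .core import IbiSeries, PpgRecording, empty_ibi_series

DEFAULT_OFFSET_GRID = np.arange(5, 305, 5)   # percent of signal RMS
BPM_RANGE = (40.0, 180.0)


def bandpass(rec: PpgRecording, low: float = 0.7, high: float = 3.5,
             order: int = 3) -> PpgRecording:
    """Zero-phase Butterworth bandpass; preserves length and beat timing.

    Defaults bracket plausible heart rates (42-210 bpm). Applied
    forward-backward so detected peak positions are not phase-shifted;
    order 3 keeps the two-pass passband loss at a 1 Hz pulse under 3%
    while still attenuating 0.1 Hz drift by far more than 20 dB.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= rec.fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below the Nyquist "
                         f"frequency {rec.fs / 2} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                     output="sos")
    return rec.with_samples(sps.sosfiltfilt(sos, rec.samples))


def _candidate_peaks(sig: np.ndarray, ma: np.ndarray,
                     offset: float) -> np.ndarray:
    """One peak (argmax) per contiguous region where sig > ma + offset."""
    above = sig > ma + offset
    if not above.any():
        return np.empty(0, dtype=int)
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    peaks = [region[np.argmax(sig[region])]
             for region in np.split(idx, splits)]
    return np.asarray(peaks, dtype=int)


def _parabolic_refine(sig: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample vertex positions via 3-point parabola around each maximum."""
    refined = peaks.astype(float)
    inner = (peaks > 0) & (peaks < sig.size - 1)
    p = peaks[inner]
    denom = sig[p - 1] - 2 * sig[p] + sig[p + 1]
    ok = denom < 0
    delta = np.zeros(p.size)
    delta[ok] = 0.5 * (sig[p - 1] - sig[p + 1])[ok] / denom[ok]
    refined[inner] = p + np.clip(delta, -0.5, 0.5)
    return refined


def detect_peaks(rec: PpgRecording, *, ma_window_s: float = 0.75,
                 offset_grid_pct: np.ndarray = DEFAULT_OFFSET_GRID
                 ) -> np.ndarray:
    """Locate heartbeats in a bandpassed recording.

    A moving average (0.75 s window) tracks the local baseline; regions where
    the signal exceeds the moving average plus an amplitude-scaled offset
    become beat candidates, one beat per region at the region maximum. The
    offset is chosen adaptively: every value on a percent grid of the signal
    RMS is tried and the one whose implied beat rate is physiological
    (40-180 bpm) with minimal IBI dispersion is kept. Positions are refined
    to sub-sample precision by parabolic interpolation.

    Returns float sample positions (divide by ``rec.fs`` for seconds);
    empty with a warning when no threshold yields candidates.
    """
    if rec.duration_s < 10.0:
        raise ValueError("need at least 10 s of signal for peak detection")
    sig = rec.samples
    rms = float(np.sqrt(np.mean(sig ** 2)))
    if rms == 0:
        warnings.warn("flat signal: no beats detected", stacklevel=2)
        return np.empty(0)
    ma = uniform_filter1d(sig, size=max(int(ma_window_s * rec.fs), 1),
                          mode="nearest")
    best: np.ndarray | None = None
    best_score = np.inf
    duration_min = rec.duration_s / 60.0
    for pct in offset_grid_pct:
        peaks = _candidate_peaks(sig, ma, pct / 100.0 * rms)
        if peaks.size < 2:
            continue
        ibis = np.diff(peaks) / rec.fs * 1000.0
        bpm = peaks.size / duration_min
        if not BPM_RANGE[0] <= bpm <= BPM_RANGE[1]:
            continue
        score = float(np.std(ibis))
        if score < best_score:
            best_score = score
            best = peaks
    if best is None:
        warnings.warn("no plausible beat threshold found; empty result",
                      stacklevel=2)
        return np.empty(0)
    return _parabolic_refine(sig, best)


def peaks_to_ibis(beats: np.ndarray, fs: float, *, subject_id: str = "",
                  start_time=None) -> IbiSeries:
    """Convert refined beat positions (samples) to an IBI series (ms).

    Fewer than 2 beats gives an empty series; unsorted or duplicate
    positions raise.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.size >= 2 and np.any(np.diff(beats) <= 0):
        raise ValueError("beat positions must be strictly increasing")
    if beats.size < 2:
        return empty_ibi_series(subject_id=subject_id, start_time=start_time)
    return IbiSeries.from_beat_times(beats / fs, subject_id=subject_id,
                                     start_time=start_time)


def filter_ibis(series: IbiSeries, window_s: float = 300.0,
                threshold: float = 0.30) -> IbiSeries:
    """Reject IBIs deviating more than ``threshold`` from their segment mean.

    The recording is cut into half-open ``window_s`` segments from its start;
    within each, the mean over the raw (pre-rejection) IBIs defines the
    acceptance band [mean*(1-threshold), mean*(1+threshold)]. Rejection only
    clears the accepted mask — nothing is deleted — and because the band is
    computed from the raw IBIs in a single pass the operation is idempotent.
    """
    if series.is_empty:
        return series
    seg = np.floor(series.beat_times[:-1] / window_s).astype(int)
    accepted = series.accepted.copy()
    for s in np.unique(seg):
        in_seg = seg == s
        m = series.ibis_ms[in_seg].mean()
        lo, hi = m * (1 - threshold), m * (1 + threshold)
        accepted[in_seg] &= (series.ibis_ms[in_seg] >= lo) & \
                            (series.ibis_ms[in_seg] <= hi)
    return IbiSeries(series.beat_times, series.ibis_ms, accepted,
                     subject_id=series.subject_id,
                     start_time=series.start_time)


def extract_ibis(rec: PpgRecording, *, low: float = 0.7, high: float = 3.5,
                 window_s: float = 300.0,
                 threshold: float = 0.30) -> IbiSeries:
    """Full per-recording chain: bandpass -> peaks -> IBIs -> 30% filter."""
    filtered = bandpass(rec, low, high)
    beats = detect_peaks(filtered)
    series = peaks_to_ibis(beats, rec.fs, subject_id=rec.subject_id,
                           start_time=rec.start_time)
    return filter_ibis(series, window_s=window_s, threshold=threshold)
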