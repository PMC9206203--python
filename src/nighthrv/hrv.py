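"""Time- and frequency-domain HRV per 5-minute window, raw and HR-normalized.

Heart rate itself changes substantially across pregnancy, and most HRV
indices co-vary with mean heart rate; to separate variability changes from
rate changes each metric is also computed on IBIs divided by the window's
mean IBI and scaled by 100. On that convention nSDNN is a percent
coefficient of variation of the interbeat interval, and every normalized
metric (and both spectral ratios) is invariant under a uniform rescaling of
the IBIs, while the raw metrics scale linearly (quadratically for band
powers).

Spectral estimation: the unevenly sampled tachogram is cubic-spline
interpolated to a uniform 4 Hz grid and a Welch periodogram (120 s Hann
segments, 50% overlap, per-segment mean removal) is integrated over
0.04-0.15 Hz (LF) and 0.15-0.4 Hz (HF). A Lomb-Scargle estimator that works
on the uneven beat times directly is available for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import IbiSeries, UndefinedWindowError

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
NORMALIZATION_SCALE = 100.0

HRV_COLUMNS = ["HR", "AVNN", "SDNN", "nSDNN", "RMSSD", "nRMSSD",
               "LF", "nLF", "HF", "nHF", "LF_HF", "nLF_nHF"]


def time_domain(ibis_ms: np.ndarray, accepted: np.ndarray | None = None
                ) -> tuple[float, float, float]:
    """AVNN, SDNN, RMSSD over the accepted IBIs of one window.

    AVNN is the mean, SDNN the sample standard deviation (n-1 denominator),
    and RMSSD the root mean square of differences between *adjacent* accepted
    IBIs — pairs separated by a rejected interval are excluded rather than
    bridged. RMSSD is NaN when no adjacent accepted pair exists.
    """
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if accepted is None:
        accepted = np.ones(ibis_ms.size, dtype=bool)
    accepted = np.asarray(accepted, dtype=bool)
    acc = ibis_ms[accepted]
    if acc.size < 2:
        raise UndefinedWindowError("need at least 2 accepted IBIs")
    avnn = float(acc.mean())
    sdnn = float(acc.std(ddof=1))
    pair = accepted[:-1] & accepted[1:]
    if pair.any():
        d = np.diff(ibis_ms)[pair]
        rmssd = float(np.sqrt(np.mean(d ** 2)))
    else:
        rmssd = float("nan")
    return avnn, sdnn, rmssd


def heart_rate(ibis_ms: np.ndarray, accepted: np.ndarray | None = None
               ) -> float:
    """Heart rate in beats per minute from the mean accepted IBI."""
    avnn, _, _ = time_domain(ibis_ms, accepted)
    return 60000.0 / avnn


def normalize_ibis(ibis_ms: np.ndarray,
                   scale: float = NORMALIZATION_SCALE) -> np.ndarray:
    """Divide IBIs by their mean (scaled x100): mean of the result is 100."""
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if ibis_ms.size < 2:
        raise UndefinedWindowError("need at least 2 IBIs to normalize")
    return scale * ibis_ms / ibis_ms.mean()


def _band_power(fxx: np.ndarray, pxx: np.ndarray,
                band: tuple[float, float]) -> float:
    mask = (fxx >= band[0]) & (fxx < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[mask], fxx[mask]))


def frequency_domain(beat_times_s: np.ndarray, ibis_ms: np.ndarray,
                     accepted: np.ndarray | None = None, *,
                     fs_interp: float = 4.0, welch_window_s: float = 120.0,
                     method: str = "welch"
                     ) -> tuple[float, float, float]:
    """LF and HF band power (ms^2) and their ratio for one window.

    ``beat_times_s`` are the beat times bounding the IBIs (length
    ``len(ibis_ms) + 1``); each IBI is placed at its ending beat time.
    The ratio is NaN (with a warning) when HF power is zero.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if accepted is None:
        accepted = np.ones(ibis_ms.size, dtype=bool)
    t = beat_times_s[1:][accepted]
    y = ibis_ms[accepted]
    if t.size < 4:
        raise UndefinedWindowError("too few accepted IBIs for a spectrum")
    span = t[-1] - t[0]
    if span < 240.0:
        raise UndefinedWindowError("window must span at least 240 s of beats")
    if method == "welch":
        grid = np.arange(t[0], t[-1], 1.0 / fs_interp)
        tach = CubicSpline(t, y)(grid)
        nperseg = min(int(welch_window_s * fs_interp), tach.size)
        fxx, pxx = sps.welch(tach, fs=fs_interp, nperseg=nperseg,
                             noverlap=nperseg // 2, detrend="constant")
    elif method == "lombscargle":
        fxx = np.arange(0.005, HF_BAND[1] + 0.05, 0.005)
        pxx_ls = sps.lombscargle(t, y - y.mean(), 2 * np.pi * fxx)
        # convert to one-sided density (ms^2/Hz)
        pxx = pxx_ls * 4.0 / t.size / (2 * np.pi) * np.pi
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    lf = _band_power(fxx, pxx, LF_BAND)
    hf = _band_power(fxx, pxx, HF_BAND)
    if hf > 0:
        ratio = lf / hf
    else:
        warnings.warn("HF power is zero; LF/HF undefined", stacklevel=2)
        ratio = float("nan")
    return lf, hf, ratio


@dataclass
class HrvWindow:
    """One 5-minute window's HR plus raw and normalized HRV parameters."""

    subject_id: str
    window_start: object          # datetime when known, else seconds offset
    n_beats: int
    HR: float
    AVNN: float
    SDNN: float
    nSDNN: float
    RMSSD: float
    nRMSSD: float
    LF: float
    nLF: float
    HF: float
    nHF: float
    LF_HF: float
    nLF_nHF: float


def window_hrv(series: IbiSeries, *, window_s: float = 300.0,
               min_beats: int = 150, spectral_method: str = "welch"
               ) -> pd.DataFrame:
    """Cut an IBI series into non-overlapping 5-minute windows and score each.

    Windows are half-open, anchored at the recording start; a trailing
    remainder shorter than ``window_s`` is discarded, and windows with fewer
    than ``min_beats`` accepted IBIs are skipped. Normalized parameters are
    computed per window: the window's IBIs are divided by the window mean
    (x100) and the identical time-domain and spectral pipelines are rerun on
    the normalized sequence.
    """
    rows: list[dict] = []
    if series.is_empty:
        return pd.DataFrame(columns=["subject_id", "window_start",
                                     "n_beats"] + HRV_COLUMNS)
    n_windows = int(series.beat_times[-1] // window_s)
    for k in range(n_windows):
        lo, hi = k * window_s, (k + 1) * window_s
        in_win = (series.beat_times[:-1] >= lo) & \
                 (series.beat_times[:-1] < hi)
        if not in_win.any():
            continue
        idx = np.flatnonzero(in_win)
        bt = series.beat_times[idx[0]:idx[-1] + 2]
        ibis = series.ibis_ms[idx]
        acc = series.accepted[idx]
        if acc.sum() < min_beats:
            continue
        avnn, sdnn, rmssd = time_domain(ibis, acc)
        hr = 60000.0 / avnn
        norm = ibis * NORMALIZATION_SCALE / ibis[acc].mean()
        _, nsdnn, nrmssd = time_domain(norm, acc)
        try:
            lf, hf, lf_hf = frequency_domain(bt, ibis, acc,
                                             method=spectral_method)
            nlf, nhf, nratio = frequency_domain(bt, norm, acc,
                                                method=spectral_method)
        except UndefinedWindowError:
            lf = hf = lf_hf = nlf = nhf = nratio = float("nan")
        start = series.start_time + timedelta(seconds=lo) \
            if series.start_time is not None else lo
        rows.append(asdict(HrvWindow(
            subject_id=series.subject_id, window_start=start,
            n_beats=int(acc.sum()), HR=hr, AVNN=avnn, SDNN=sdnn,
            nSDNN=nsdnn, RMSSD=rmssd, nRMSSD=nrmssd, LF=lf, nLF=nlf,
            HF=hf, nHF=nhf, LF_HF=lf_hf, nLF_nHF=nratio)))
    return pd.DataFrame(rows, columns=["subject_id", "window_start",
                                       "n_beats"] + HRV_COLUMNS)
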