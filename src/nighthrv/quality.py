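"""Per-segment PPG reliability screening.

Wrist PPG is contaminated by motion and ambient-light artifacts; reliable
stretches share a repetitive pulse waveform while artifacts are morphologically
diverse. Each segment is summarised by five features — skewness, kurtosis,
approximate entropy, Shannon entropy and spectral entropy — and a support
vector machine (RBF kernel, z-scored inputs) separates reliable from
unreliable segments. Unreliable segments are dropped before beat detection.

Estimator conventions (the classifier, not the features, is the decision
maker, so these only need to be fixed and documented):

* approximate entropy with m=2, r=0.2*SD, computed on the first 60 s of the
  standardized segment (the O(n^2) statistic saturates well before that);
* Shannon entropy (bits) on a 32-bin amplitude histogram of the standardized
  segment;
* spectral entropy = entropy of the normalized Welch power spectrum divided
  by log(#bins), hence in [0, 1].

All features are computed on the amplitude-standardized segment, so labels
are invariant under rescaling of the raw signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import DegenerateSegmentError, PpgRecording

FEATURE_NAMES = ["skewness", "kurtosis", "approximate_entropy",
                 "shannon_entropy", "spectral_entropy"]

_APEN_MAX_SAMPLES = 1200   # 60 s at the study's 20 Hz


@dataclass
class QualityFeatures:
    skewness: float
    kurtosis: float                 # Pearson convention (Gaussian -> 3)
    approximate_entropy: float
    shannon_entropy: float          # bits
    spectral_entropy: float         # normalized, in [0, 1]

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_NAMES])


def _approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """ApEn(m, r) with Chebyshev distance; x is already unit-variance."""
    x = x[:_APEN_MAX_SAMPLES]
    n = x.size

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def _shannon_entropy(x: np.ndarray, bins: int = 32) -> float:
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _spectral_entropy(x: np.ndarray, fs: float) -> float:
    nperseg = min(x.size, 256)
    _, pxx = sps.welch(x, fs=fs, nperseg=nperseg)
    pxx = pxx[pxx > 0]
    p = pxx / pxx.sum()
    return float(-(p * np.log(p)).sum() / np.log(p.size))


def extract_quality_features(segment: PpgRecording) -> QualityFeatures:
    """Compute the five morphological/entropy features for one segment.

    Raises
    ------
    DegenerateSegmentError
        if the segment is constant (moments undefined) or shorter than 10 s.
    """
    x = np.asarray(segment.samples, dtype=float)
    if segment.duration_s < 10.0:
        raise ValueError("segment must be at least 10 s long")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    sd = x.std()
    if sd == 0 or np.ptp(x) == 0:
        raise DegenerateSegmentError("constant segment: features undefined")
    z = (x - x.mean()) / sd
    return QualityFeatures(
        skewness=float(stats.skew(z)),
        kurtosis=float(stats.kurtosis(z, fisher=False)),
        approximate_entropy=_approximate_entropy(z),
        shannon_entropy=_shannon_entropy(z),
        spectral_entropy=_spectral_entropy(z, segment.fs),
    )


def is_degenerate(segment: PpgRecording) -> bool:
    """True for constant segments, whose features are undefined.

    Such segments never reach the classifier: they are labelled unreliable
    directly, so training sets should filter them with this predicate.
    """
    return float(np.ptp(np.asarray(segment.samples))) == 0.0


def features_frame(segments: list[PpgRecording]) -> pd.DataFrame:
    """Feature table for a list of segments (rows align with the input)."""
    return pd.DataFrame([asdict(extract_quality_features(s))
                         for s in segments])


@dataclass
class QualityModel:
    """Fitted SVM with its standardization, feature order and seed."""

    pipeline: Pipeline
    feature_names: list[str]
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Return boolean reliability per row of a feature table."""
        x = features[self.feature_names].to_numpy()
        return self.pipeline.predict(x) == 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.pipeline, path)
        sidecar = {"feature_names": self.feature_names, "seed": self.seed,
                   "format_version": 1,
                   "scaler_mean": self.pipeline["scaler"].mean_.tolist(),
                   "scaler_scale": self.pipeline["scaler"].scale_.tolist()}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "QualityModel":
        path = Path(path)
        pipeline = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(pipeline=pipeline, feature_names=meta["feature_names"],
                   seed=meta["seed"])


def train_quality_classifier(features: pd.DataFrame, labels,
                             seed: int = 0) -> QualityModel:
    """Fit the reliable/unreliable SVM on a labelled feature table.

    ``labels`` may be boolean or the strings "reliable"/"unreliable".
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = (y == "reliable")
    y = y.astype(int)
    if len(features) < 10:
        raise ValueError("need at least 10 labelled segments")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the labels")
    x = features[FEATURE_NAMES].to_numpy()
    pipe = Pipeline([
        ("scaler", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)),
    ])
    pipe.fit(x, y)
    return QualityModel(pipeline=pipe, feature_names=list(FEATURE_NAMES),
                        seed=seed)


def classify_segments(recordings: list[PpgRecording], model: QualityModel,
                      *, subsegment_s: float = 300.0,
                      min_duration_s: float = 10.0
                      ) -> tuple[np.ndarray, dict[str, int]]:
    """Label each recording reliable/unreliable.

    Features are evaluated per complete ``subsegment_s`` stretch (aligned
    with the HRV windows); a recording is reliable iff every evaluated
    stretch classifies reliable. Segments too short or constant are labelled
    unreliable with a warning rather than dropped silently.

    Returns
    -------
    mask : boolean array, one entry per recording (True = reliable)
    counts : dict with keys ``reliable``, ``unreliable``, ``total``
    """
    mask = np.zeros(len(recordings), dtype=bool)
    for i, rec in enumerate(recordings):
        n_sub = int(rec.duration_s // subsegment_s)
        pieces: list[PpgRecording] = []
        if n_sub == 0:
            if rec.duration_s < min_duration_s:
                warnings.warn(f"segment {i} shorter than {min_duration_s} s; "
                              "labelled unreliable", stacklevel=2)
                continue
            pieces = [rec]
        else:
            step = int(subsegment_s * rec.fs)
            pieces = [rec.with_samples(rec.samples[k * step:(k + 1) * step])
                      for k in range(n_sub)]
        try:
            feats = features_frame(pieces)
        except DegenerateSegmentError:
            mask[i] = False
            continue
        mask[i] = bool(model.predict(feats).all())
    counts = {"reliable": int(mask.sum()),
              "unreliable": int((~mask).sum()) if len(recordings) else 0,
              "total": len(recordings)}
    return mask, counts
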