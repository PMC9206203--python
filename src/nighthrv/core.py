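"""Core containers shared across the pipeline stages.

A :class:`PpgRecording` is one contiguous, uniformly sampled stretch of
photoplethysmogram; an :class:`IbiSeries` is the beat-to-beat interval
sequence extracted from it, carrying an accepted/rejected mask so that
artifact handling never silently deletes data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd


class DegenerateSegmentError(ValueError):
    """Raised when a segment is constant (moments/entropies undefined)."""


class UndefinedWindowError(ValueError):
    """Raised when a window has too few accepted beats for a metric."""


@dataclass
class PpgRecording:
    """One timestamped raw PPG segment for one subject at a fixed rate.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    start_time : datetime
        Wall-clock time of the first sample (naive local time).
    fs : float
        Sampling frequency in Hz (the study devices record at 20 Hz).
    samples : ndarray
        Signal in arbitrary units.
    """

    subject_id: str
    start_time: datetime
    fs: float
    samples: np.ndarray
    quality_label: str | None = None  # "reliable"/"unreliable" if known

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a recording needs at least 2 samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, **kw) -> "PpgRecording":
        return replace(self, samples=np.asarray(samples, dtype=float), **kw)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a two-column table (ISO-8601 timestamp, ppg a.u.)."""
        ts = pd.date_range(self.start_time, periods=self.samples.size,
                           freq=pd.Timedelta(seconds=1.0 / self.fs))
        return pd.DataFrame({"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                             "ppg": self.samples})


@dataclass
class IbiSeries:
    """Beat times and interbeat intervals with an accepted mask.

    ``ibis_ms[k]`` is the interval between ``beat_times[k]`` and
    ``beat_times[k+1]``; rejecting an interval only flips its mask bit,
    so provenance stays auditable.
    """

    beat_times: np.ndarray        # seconds from recording start
    ibis_ms: np.ndarray           # milliseconds, length = len(beat_times) - 1
    accepted: np.ndarray          # bool per IBI
    subject_id: str = ""
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis_ms = np.asarray(self.ibis_ms, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        n = self.beat_times.size
        if self.ibis_ms.size != max(n - 1, 0):
            raise ValueError("ibis_ms must have len(beat_times) - 1 entries")
        if self.accepted.size != self.ibis_ms.size:
            raise ValueError("accepted mask must align with ibis_ms")
        if n > 1:
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat times must be strictly increasing")
            if not np.allclose(self.ibis_ms,
                               np.diff(self.beat_times) * 1000.0,
                               rtol=0, atol=1e-6):
                raise ValueError("ibis_ms inconsistent with beat_times")

    def __len__(self) -> int:
        return self.ibis_ms.size

    @property
    def is_empty(self) -> bool:
        return self.ibis_ms.size == 0

    def to_frame(self) -> pd.DataFrame:
        """Checkpoint format: subject_id, beat_time_s, ibi_ms, accepted."""
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "beat_time_s": self.beat_times[1:],
            "ibi_ms": self.ibis_ms,
            "accepted": self.accepted,
        })

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray, *, subject_id: str = "",
                        start_time: datetime | None = None) -> "IbiSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        ibis = np.diff(beat_times) * 1000.0
        return cls(beat_times, ibis, np.ones(ibis.size, dtype=bool),
                   subject_id=subject_id, start_time=start_time)


def empty_ibi_series(subject_id: str = "",
                     start_time: datetime | None = None) -> IbiSeries:
    return IbiSeries(np.empty(0), np.empty(0), np.empty(0, dtype=bool),
                     subject_id=subject_id, start_time=start_time)
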