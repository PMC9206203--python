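"""Shared fixtures: small synthetic signals and a labelled quality corpus."""

from __future__ import annotations

import numpy as np
import pytest

import nighthrv as nh
from nighthrv.quality import features_frame


@pytest.fixture(scope="session")
def clean_profile() -> nh.IbiProfile:
    """Modulated beat process typical of a resting adult (HR 65 bpm)."""
    return nh.IbiProfile(mean_ibi_ms=920, lf_amp_ms=40, hf_amp_ms=30,
                         jitter_sd_ms=5, duration_s=300)


@pytest.fixture(scope="session")
def clean_recording(clean_profile):
    """One clean 5-minute rendered PPG segment with its true beats."""
    beats, ibis = nh.simulate_ibi_series(clean_profile, seed=7)
    rec = nh.render_ppg(beats, fs=20.0, duration_s=300)
    return rec, beats, ibis


@pytest.fixture(scope="session")
def quality_corpus():
    """120 labelled 60-s segments: clean pulses vs corrupted copies.

    Flatline corruptions are excluded here (they are rejected before the
    classifier by the degeneracy rule), so the corpus exercises the SVM on
    the two non-trivial artifact families.
    """
    rng = np.random.default_rng(42)
    segments, labels = [], []
    for i in range(60):
        profile = nh.IbiProfile(mean_ibi_ms=900 + rng.uniform(-150, 150),
                                lf_amp_ms=40, hf_amp_ms=30, jitter_sd_ms=5,
                                duration_s=60)
        beats, _ = nh.simulate_ibi_series(profile, int(rng.integers(2 ** 31)))
        rec = nh.render_ppg(beats, fs=20.0, duration_s=60)
        segments.append(rec)
        labels.append("reliable")
        mode = ("gaussian_noise", "motion_burst")[i % 2]
        severity = 5.0 if mode == "gaussian_noise" else 8.0
        segments.append(nh.corrupt_segment(rec, mode, severity,
                                           int(rng.integers(2 ** 31))))
        labels.append("unreliable")
    return segments, np.array(labels)


@pytest.fixture(scope="session")
def quality_features(quality_corpus):
    segments, labels = quality_corpus
    return features_frame(segments), labels
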