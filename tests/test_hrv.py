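"""Time/frequency HRV oracles, HR-normalization conventions and the
scale-equivariance contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nighthrv as nh
from nighthrv.core import IbiSeries, UndefinedWindowError
from nighthrv.hrv import (frequency_domain, heart_rate, normalize_ibis,
                          time_domain, window_hrv)


def _naive_time_domain(ibis, accepted):
    """Double-loop reference implementation (the oracle)."""
    acc = [x for x, a in zip(ibis, accepted) if a]
    n = len(acc)
    avnn = sum(acc) / n
    sdnn = (sum((x - avnn) ** 2 for x in acc) / (n - 1)) ** 0.5
    sq, m = 0.0, 0
    for k in range(len(ibis) - 1):
        if accepted[k] and accepted[k + 1]:
            sq += (ibis[k + 1] - ibis[k]) ** 2
            m += 1
    rmssd = (sq / m) ** 0.5 if m else float("nan")
    return avnn, sdnn, rmssd


class TestTimeDomain:
    def test_constant_ibis(self):
        avnn, sdnn, rmssd = time_domain(np.full(10, 1000.0))
        assert (avnn, sdnn, rmssd) == (1000.0, 0.0, 0.0)

    def test_alternating_rmssd_exact(self):
        ibis = np.tile([800.0, 810.0], 10)
        avnn, sdnn, rmssd = time_domain(ibis)
        assert rmssd == pytest.approx(10.0, abs=1e-12)
        assert avnn == pytest.approx(805.0)

    def test_hand_checkable(self):
        avnn, _, rmssd = time_domain(np.array([800.0, 900.0, 1000.0]))
        assert avnn == pytest.approx(900.0)
        assert rmssd == pytest.approx(100.0)

    def test_rejected_gap_not_bridged(self):
        ibis = np.array([1000.0, 5000.0, 1000.0, 1010.0])
        acc = np.array([True, False, True, True])
        _, _, rmssd = time_domain(ibis, acc)
        # only the (1000, 1010) pair is adjacent-accepted
        assert rmssd == pytest.approx(10.0)

    def test_oracle_equivalence_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 60)
            ibis = rng.uniform(500, 1500, n)
            acc = rng.uniform(size=n) > 0.2
            if acc.sum() < 2:
                continue
            ours = time_domain(ibis, acc)
            ref = _naive_time_domain(list(ibis), list(acc))
            for a, b in zip(ours, ref):
                if np.isnan(a) and np.isnan(b):
                    continue
                assert a == pytest.approx(b, rel=1e-9)

    def test_too_few_ibis_rejected(self):
        with pytest.raises(UndefinedWindowError):
            time_domain(np.array([1000.0]))


class TestHeartRate:
    @pytest.mark.parametrize("avnn,expected", [(1000.0, 60.0),
                                               (845.0, 71.0),
                                               (500.0, 120.0)])
    def test_hr_from_mean_ibi(self, avnn, expected):
        hr = heart_rate(np.full(10, avnn))
        assert hr == pytest.approx(expected, abs=0.01)


class TestNormalization:
    def test_percent_convention(self):
        out = normalize_ibis(np.array([900.0, 1000.0, 1100.0]))
        assert np.allclose(out, [90.0, 100.0, 110.0])
        assert out.mean() == pytest.approx(100.0, abs=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_scale_invariance(self, c):
        ibis = np.array([800.0, 950.0, 1100.0, 1020.0])
        assert np.allclose(normalize_ibis(ibis), normalize_ibis(c * ibis))

    def test_equal_ibis_give_constant_100(self):
        out = normalize_ibis(np.full(20, 837.0))
        assert np.allclose(out, 100.0)
        _, nsdnn, _ = time_domain(out)
        assert nsdnn == 0.0


def _sinusoid_series(freq, amp, duration=300.0, mean=1000.0, seed=0):
    beats, ibis = nh.simulate_ibi_series(
        nh.IbiProfile(mean, amp if freq < 0.15 else 0.0,
                      amp if freq >= 0.15 else 0.0, 0.0, duration), seed)
    return beats, ibis


class TestFrequencyDomain:
    def test_constant_tachogram_zero_power(self):
        beats = np.arange(0, 301.0)
        ibis = np.full(300, 1000.0)
        lf, hf, _ = frequency_domain(beats, ibis)
        assert lf < 1e-6 and hf < 1e-6

    def test_hf_modulation_lands_in_hf(self):
        beats, ibis = _sinusoid_series(0.25, 50.0)
        lf, hf, ratio = frequency_domain(beats, ibis)
        assert hf / (lf + hf) >= 0.95
        assert ratio < 0.1
        # Parseval: total band power ~ sinusoid variance 50^2/2
        assert lf + hf == pytest.approx(1250.0, rel=0.10)

    def test_lf_modulation_lands_in_lf(self):
        beats, ibis = _sinusoid_series(0.10, 50.0)
        lf, hf, ratio = frequency_domain(beats, ibis)
        assert lf / (lf + hf) >= 0.95
        assert ratio > 10

    def test_lombscargle_agrees_on_band_assignment(self):
        beats, ibis = _sinusoid_series(0.25, 50.0)
        lf, hf, _ = frequency_domain(beats, ibis, method="lombscargle")
        assert hf / (lf + hf) >= 0.95

    def test_short_span_rejected(self):
        beats = np.arange(0, 100.0)
        with pytest.raises(UndefinedWindowError):
            frequency_domain(beats, np.full(99, 1000.0))


class TestWindowHrv:
    @pytest.fixture(scope="class")
    def twelve_minute_series(self):
        beats, _ = nh.simulate_ibi_series(
            nh.IbiProfile(920, 40, 30, 5, 720), seed=3)
        return IbiSeries.from_beat_times(beats, subject_id="S0")

    def test_twelve_minutes_gives_two_windows(self, twelve_minute_series):
        wins = window_hrv(twelve_minute_series)
        assert len(wins) == 2

    def test_underpopulated_window_skipped(self):
        beats, _ = nh.simulate_ibi_series(
            nh.IbiProfile(1800, 0, 0, 0, 610), seed=0)   # ~33 bpm, ~167/win
        wins = window_hrv(IbiSeries.from_beat_times(beats), min_beats=200)
        assert wins.empty

    def test_sdnn_matches_analytic_target(self):
        profile = nh.IbiProfile(900, 40, 30, 0, 310)
        beats, _ = nh.simulate_ibi_series(profile, seed=1)
        wins = window_hrv(IbiSeries.from_beat_times(beats))
        assert len(wins) == 1
        assert wins.SDNN[0] == pytest.approx(profile.asymptotic_sdnn_ms,
                                             rel=0.05)
        # invariant HR * AVNN ~ 60000 on clean windows
        assert wins.HR[0] * wins.AVNN[0] == pytest.approx(60000, rel=0.02)

    def test_scale_equivariance_of_metrics(self, twelve_minute_series):
        """Multiplying the IBI values by c (same sample times) scales
        AVNN/SDNN/RMSSD by c and LF/HF by c^2, leaves every normalized
        metric and both spectral ratios unchanged, and divides HR by c —
        the purpose of HR-normalization, asserted directly."""
        s = twelve_minute_series
        bt = s.beat_times[:302]
        ibis = s.ibis_ms[:301]
        c = 1.25
        a_t = time_domain(ibis)
        b_t = time_domain(c * ibis)
        assert np.allclose(b_t, tuple(c * x for x in a_t), rtol=1e-12)
        assert heart_rate(c * ibis) == pytest.approx(heart_rate(ibis) / c)
        a_f = frequency_domain(bt, ibis)
        b_f = frequency_domain(bt, c * ibis)
        assert b_f[0] == pytest.approx(c ** 2 * a_f[0], rel=1e-9)
        assert b_f[1] == pytest.approx(c ** 2 * a_f[1], rel=1e-9)
        assert b_f[2] == pytest.approx(a_f[2], rel=1e-9)
        # normalized pipeline is fully invariant
        na, nb = normalize_ibis(ibis), normalize_ibis(c * ibis)
        assert np.allclose(na, nb, rtol=1e-12)
        assert np.allclose(frequency_domain(bt, na),
                           frequency_domain(bt, nb), rtol=1e-9)

    def test_exact_scale_equivariance_time_domain(self):
        """The pure functions obey equivariance exactly, not just at window
        level where windowing boundaries can shift."""
        rng = np.random.default_rng(5)
        ibis = rng.uniform(700, 1300, 50)
        c = 3.0
        a = time_domain(ibis)
        b = time_domain(c * ibis)
        assert np.allclose(b, tuple(c * x for x in a), rtol=1e-12)
        assert np.allclose(normalize_ibis(ibis), normalize_ibis(c * ibis))
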