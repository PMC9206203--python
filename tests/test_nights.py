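"""Night-window selection, nightly summaries, obstetric period labelling
and the reliability accounting table."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from nighthrv.hrv import HRV_COLUMNS
from nighthrv.nights import (assign_period, night_reliability_counts,
                             nightly_summary, reliability_report,
                             select_night_windows)


def _windows(starts, hr=None):
    n = len(starts)
    df = pd.DataFrame({c: np.linspace(50, 60, n) for c in HRV_COLUMNS})
    df["window_start"] = pd.to_datetime(starts)
    df["subject_id"] = "S0"
    df["n_beats"] = 300
    if hr is not None:
        df["HR"] = hr
    return df


class TestSelectNightWindows:
    @pytest.mark.parametrize("ts,kept", [
        ("2020-03-01 01:30:00", True),
        ("2020-03-01 23:55:00", False),
        ("2020-03-01 06:00:00", False),   # half-open upper boundary
        ("2020-03-01 00:00:00", True),    # closed lower boundary
        ("2020-03-01 05:59:59", True),
    ])
    def test_boundaries(self, ts, kept):
        out = select_night_windows(_windows([ts]))
        assert (len(out) == 1) == kept

    def test_empty_frame(self):
        out = select_night_windows(_windows([]))
        assert out.empty


class TestNightlySummary:
    def test_single_window_identity(self):
        w = _windows(["2020-03-01 02:00:00"], hr=[58.0])
        rec = nightly_summary(w)
        assert rec["HR"] == 58.0
        assert rec["n_windows_used"] == 1

    def test_min_hr_window_supplies_all_values(self):
        w = _windows(["2020-03-01 01:00", "2020-03-01 02:00",
                      "2020-03-01 03:00"], hr=[62.0, 58.0, 65.0])
        w.loc[:, "SDNN"] = [40.0, 55.0, 70.0]
        rec = nightly_summary(w, mode="min_hr")
        # brute-force argmin: HR 58 is row 1, so SDNN must be 55
        assert rec["HR"] == 58.0
        assert rec["SDNN"] == 55.0

    def test_mean_mode(self):
        w = _windows(["2020-03-01 01:00", "2020-03-01 02:00"])
        w.loc[:, "SDNN"] = [50.0, 70.0]
        rec = nightly_summary(w, mode="mean")
        assert rec["SDNN"] == 60.0

    def test_zero_windows_rejected(self):
        with pytest.raises(ValueError):
            nightly_summary(_windows([]))


class TestAssignPeriod:
    # enrolment at gestational day 112 (week 16)
    ENROL = date(2020, 1, 6)
    GA0 = 112

    def test_week_20_is_trimester2(self):
        night = date(2020, 2, 3)          # +28 d -> GA 140 d = week 20
        period, day_in, week, _ = assign_period(night, self.ENROL, self.GA0,
                                                date(2020, 6, 29))
        assert period == "trimester2"
        assert week == 20
        assert day_in == 28

    def test_week_30_is_trimester3(self):
        night = date(2020, 4, 13)         # +98 d -> GA 210 d = week 30
        period, day_in, week, preterm = assign_period(
            night, self.ENROL, self.GA0, date(2020, 6, 29))
        assert period == "trimester3"
        assert day_in == 7
        assert not preterm

    def test_postpartum_day_30(self):
        delivery = date(2020, 6, 29)
        night = delivery + pd.Timedelta(days=30).to_pytimedelta()
        period, day_in, week, _ = assign_period(night, self.ENROL, self.GA0,
                                                delivery)
        assert period == "postpartum"
        assert day_in == 30
        assert week == 5

    def test_preterm_delivery_flagged(self):
        # delivery at GA 238 d = week 34
        delivery = date(2020, 5, 11)
        night = date(2020, 4, 20)         # GA 217 d, trimester3
        period, _, _, preterm = assign_period(night, self.ENROL, self.GA0,
                                              delivery)
        assert period == "trimester3"
        assert preterm

    def test_gaps_excluded(self):
        delivery = date(2020, 7, 20)      # GA 308 d (post week 40 gap)
        night = date(2020, 7, 10)         # GA 298 d
        period, *_ = assign_period(night, self.ENROL, self.GA0, delivery)
        assert period == "excluded"
        late = delivery + pd.Timedelta(days=90).to_pytimedelta()
        period, *_ = assign_period(late, self.ENROL, self.GA0, delivery)
        assert period == "excluded"

    def test_inconsistent_dates_rejected(self):
        with pytest.raises(ValueError):
            assign_period(date(2020, 2, 1), self.ENROL, self.GA0,
                          date(2019, 12, 1))

    def test_periods_partition_the_calendar(self):
        """No night can carry two labels; every night gets exactly one."""
        delivery = date(2020, 6, 29)
        labels = set()
        for offset in range(-10, 300, 3):
            night = self.ENROL + pd.Timedelta(days=offset).to_pytimedelta()
            period, *_ = assign_period(night, self.ENROL, self.GA0, delivery)
            labels.add(period)
            assert period in {"trimester2", "trimester3", "postpartum",
                              "excluded"}
        assert {"trimester2", "trimester3", "postpartum"} <= labels


class TestReliabilityReport:
    def test_study_scale_arithmetic(self):
        table = reliability_report({
            "trimester2": (4123, 5306),
            "trimester3": (2716, 3866),
            "postpartum": (2987, 4814),
        }).set_index("period")
        assert table.loc["trimester2", "percent_reliable"] == 77.70
        assert table.loc["trimester3", "percent_reliable"] == 70.25
        assert table.loc["postpartum", "percent_reliable"] == 62.05
        assert table.loc["total", "reliable_nights"] == 9826

    def test_percentages_recompute_from_integers(self):
        table = reliability_report({"trimester2": (3, 7)})
        row = table.set_index("period").loc["trimester2"]
        assert row["percent_reliable"] == round(100 * 3 / 7, 2)

    def test_zero_possible_flagged(self):
        table = reliability_report({"trimester2": (0, 0)})
        assert np.isnan(
            table.set_index("period").loc["trimester2", "percent_reliable"])

    def test_counts_from_segment_log(self):
        seg = pd.DataFrame({
            "subject_id": ["S0"] * 4 + ["S1"] * 2,
            "start_time": pd.to_datetime([
                "2020-03-01 02:00", "2020-03-01 04:00",   # night 1, S0
                "2020-03-02 02:00", "2020-03-02 14:00",   # night 2 + daytime
                "2020-03-01 02:00", "2020-03-01 04:00"]), # night 1, S1
            "is_night": [True, True, True, False, True, True],
            "period": ["trimester2"] * 6,
        })
        survived = np.array([False, True, False, True, False, False])
        counts = night_reliability_counts(seg, survived)
        # S0 night1 reliable (one segment survived); S0 night2 not (its only
        # night segment failed; the daytime one does not count); S1 night1 not
        assert counts["trimester2"] == (1, 3)
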