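"""Night selection, per-night summaries, period labelling and reliability.

Daytime wrist recordings are dominated by motion artifacts, so the analysis
keeps only windows starting between midnight and 6 AM, collapses each
subject-night to a single representative record (by default the window with
the minimum heart rate — the most reliably at-rest stretch of the night),
attaches the obstetric period (second trimester = gestational weeks 16-28,
third trimester = weeks 29-40, postpartum = first 12 weeks after delivery)
and the background covariates, and accounts for how many possible nights
produced a reliable record.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .hrv import HRV_COLUMNS

PERIODS = ("trimester2", "trimester3", "postpartum")
PRETERM_CUTOFF_DAYS = 37 * 7
NIGHT_HOURS = (0, 6)            # half-open [00:00, 06:00)
POSTPARTUM_DAYS = 12 * 7

# gestational-day boundaries (completed weeks): week 16 starts at day 112,
# week 29 at day 203, week 41 at day 287
_T2_START, _T3_START, _T3_END = 112, 203, 287


def select_night_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Keep HRV windows whose start lies in [00:00, 06:00) local time."""
    if windows.empty:
        return windows
    ts = pd.to_datetime(windows["window_start"])
    keep = (ts.dt.hour >= NIGHT_HOURS[0]) & (ts.dt.hour < NIGHT_HOURS[1])
    return windows.loc[keep].copy()


def nightly_summary(night_windows: pd.DataFrame,
                    mode: str = "min_hr") -> pd.Series:
    """Collapse one subject-night of windows to a single record.

    ``min_hr`` (default): the window with the minimum heart rate supplies
    every parameter — one coherent resting snapshot. ``mean``: parameter-wise
    mean across the night's windows.
    """
    if night_windows.empty:
        raise ValueError("a night needs at least one window")
    if mode == "min_hr":
        row = night_windows.loc[night_windows["HR"].idxmin(), HRV_COLUMNS]
        out = row.astype(float)
    elif mode == "mean":
        out = night_windows[HRV_COLUMNS].mean()
    else:
        raise ValueError(f"unknown nightly mode {mode!r}")
    out["n_windows_used"] = len(night_windows)
    return out


def assign_period(night_date: date, enrolment_date: date,
                  ga_at_enrolment_days: int, delivery_date: date
                  ) -> tuple[str, int, int, bool]:
    """Label one night with its obstetric period.

    Returns (period, day_in_period, week, preterm) where ``week`` is the
    completed gestational week during pregnancy or the postpartum week
    (1-based) after delivery, and ``preterm`` flags delivery before
    gestational week 37. Nights before week 16, between the end of week 40
    and delivery, or beyond 12 postpartum weeks are labelled "excluded".
    """
    if delivery_date <= enrolment_date:
        raise ValueError("delivery date must follow enrolment")
    nd = pd.Timestamp(night_date)
    ed = pd.Timestamp(enrolment_date)
    dd = pd.Timestamp(delivery_date)
    delivery_ga_days = ga_at_enrolment_days + (dd - ed).days
    preterm = delivery_ga_days < PRETERM_CUTOFF_DAYS
    if nd >= dd:
        pp_days = (nd - dd).days
        if pp_days < POSTPARTUM_DAYS:
            return "postpartum", pp_days, pp_days // 7 + 1, preterm
        return "excluded", 0, pp_days // 7 + 1, preterm
    ga_days = ga_at_enrolment_days + (nd - ed).days
    week = ga_days // 7
    if _T2_START <= ga_days < _T3_START:
        return "trimester2", ga_days - _T2_START, week, preterm
    if _T3_START <= ga_days < _T3_END:
        return "trimester3", ga_days - _T3_START, week, preterm
    return "excluded", 0, week, preterm


def build_cohort_table(windows: pd.DataFrame, covariates: pd.DataFrame,
                       mode: str = "min_hr") -> pd.DataFrame:
    """Assemble the long-format subject-night table used by the trend models.

    ``windows`` must carry ``subject_id`` and timestamped ``window_start``;
    ``covariates`` one row per subject with age, bmi, education,
    enrolment_date, ga_at_enrolment_days and delivery date information
    (either ``delivery_date`` or ``delivery_ga_days``).
    """
    night = select_night_windows(windows)
    if night.empty:
        return pd.DataFrame()
    night = night.copy()
    night["night_date"] = pd.to_datetime(night["window_start"]).dt.date
    cov = covariates.set_index("subject_id")
    rows = []
    for (sid, nd), grp in night.groupby(["subject_id", "night_date"]):
        rec = nightly_summary(grp, mode=mode)
        c = cov.loc[sid]
        enrol = pd.Timestamp(c["enrolment_date"]).date()
        ga0 = int(c["ga_at_enrolment_days"])
        if "delivery_date" in c.index and pd.notna(c.get("delivery_date")):
            delivery = pd.Timestamp(c["delivery_date"]).date()
        else:
            delivery = enrol + timedelta(days=int(c["delivery_ga_days"]) - ga0)
        period, day_in, week, preterm = assign_period(nd, enrol, ga0, delivery)
        row = {"subject_id": sid, "date": nd, "period": period,
               "day_in_period": day_in, "week": week, "preterm": preterm,
               "age": float(c["age"]), "bmi": float(c["bmi"]),
               "education": int(c["education"])}
        row.update(rec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def night_reliability_counts(segments: pd.DataFrame,
                             survived: np.ndarray) -> dict[str, tuple[int, int]]:
    """Per-period (reliable, possible) night counts from the segment log.

    A possible night is any subject-date with at least one scheduled nighttime
    segment in the period; it is reliable when at least one of its segments
    survived quality screening and beat filtering (``survived`` aligns with
    the rows of ``segments``).
    """
    seg = segments.copy()
    seg["survived"] = np.asarray(survived, dtype=bool)
    seg = seg[seg["is_night"] & seg["period"].isin(PERIODS)]
    seg["night_date"] = pd.to_datetime(seg["start_time"]).dt.date
    counts: dict[str, tuple[int, int]] = {}
    for period, grp in seg.groupby("period"):
        nights = grp.groupby(["subject_id", "night_date"])["survived"].any()
        counts[period] = (int(nights.sum()), int(nights.size))
    return counts


def reliability_report(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Reliable-night accounting table with exact percentages and totals.

    ``counts`` maps period -> (reliable, possible). Percentages are
    100*reliable/possible rounded to 2 decimals; a ``total`` row sums the
    integer counts. Zero possible nights gives a NaN percentage.
    """
    rows = []
    for period in list(counts):
        rel, poss = counts[period]
        pct = round(100.0 * rel / poss, 2) if poss > 0 else float("nan")
        rows.append({"period": period, "reliable_nights": rel,
                     "possible_nights": poss, "percent_reliable": pct})
    total_rel = sum(c[0] for c in counts.values())
    total_poss = sum(c[1] for c in counts.values())
    pct = round(100.0 * total_rel / total_poss, 2) if total_poss else float("nan")
    rows.append({"period": "total", "reliable_nights": total_rel,
                 "possible_nights": total_poss, "percent_reliable": pct})
    return pd.DataFrame(rows)
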