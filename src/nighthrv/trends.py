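"""Hierarchical linear mixed trend models over subject-nights.

Each HR/HRV parameter is regressed on days since the subject entered the
period, controlling for age, BMI and education, with a per-subject random
intercept and random slope on time to absorb between-person level and trend
differences (falling back to a random intercept when the full structure is
singular). Estimation is restricted maximum likelihood with Wald z tests.
Period comparisons add a binary period indicator as a fixed effect, with
time re-anchored to each period's own start. Subjects with preterm delivery
(before gestational week 37) are excluded from third-trimester fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

COVARIATES = ("age", "bmi", "education")


@dataclass
class TrendFit:
    """Fixed-effect estimates and tests for one parameter and period."""

    parameter: str
    period: str
    intercept: float
    intercept_p: float
    slope: float
    slope_p: float
    slope_ci: tuple[float, float]
    age_coef: float
    age_p: float
    bmi_coef: float
    bmi_p: float
    education_coef: float
    education_p: float
    period_offset: float | None = None
    period_offset_p: float | None = None
    period_offset_ci: tuple[float, float] | None = None
    random_structure: str = "intercept+slope"
    re_variances: dict = field(default_factory=dict)
    n_subjects: int = 0
    n_nights: int = 0
    converged: bool = True

    def to_row(self) -> dict:
        row = {"parameter": self.parameter, "period": self.period,
               "intercept": self.intercept, "intercept_p": self.intercept_p,
               "slope": self.slope, "slope_p": self.slope_p,
               "age_coef": self.age_coef, "age_p": self.age_p,
               "bmi_coef": self.bmi_coef, "bmi_p": self.bmi_p,
               "education_coef": self.education_coef,
               "education_p": self.education_p,
               "n_subjects": self.n_subjects, "n_nights": self.n_nights,
               "random_structure": self.random_structure}
        if self.period_offset is not None:
            row["period_offset"] = self.period_offset
            row["period_offset_p"] = self.period_offset_p
        return row


def _check_design(data: pd.DataFrame, parameter: str,
                  min_subjects: int = 5, min_nights: int = 3) -> None:
    if parameter not in data.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    per_subject = data.groupby("subject_id").size()
    ok = per_subject[per_subject >= min_nights]
    if len(ok) < min_subjects:
        raise ValueError(
            f"need at least {min_subjects} subjects with >= {min_nights} "
            f"nights; have {len(ok)}")


def _fit_mixed(data: pd.DataFrame, formula: str, parameter: str
               ) -> tuple[object, str, bool]:
    """REML fit with random intercept+slope, intercept-only fallback."""
    data = data.dropna(subset=[parameter]).copy()
    for re_formula, label in (("~day_in_period", "intercept+slope"),
                              ("1", "intercept")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                model = smf.mixedlm(formula, data, groups=data["subject_id"],
                                    re_formula=re_formula)
                res = model.fit(reml=True, method=["lbfgs", "bfgs", "cg"])
            except (np.linalg.LinAlgError, ValueError):
                res = None
        # fall back only on genuine failure: no fit, non-convergence, or
        # unusable fixed-effect standard errors
        usable = (res is not None and res.converged
                  and bool(np.all(np.isfinite(res.fe_params)))
                  and bool(np.all(np.isfinite(
                      res.bse.iloc[:len(res.fe_params)]))))
        if usable:
            return res, label, True
        if label == "intercept" and res is not None:
            warnings.warn("mixed model fit questionable even with random "
                          "intercept only", stacklevel=2)
            return res, label, bool(res.converged)
        warnings.warn("random intercept+slope structure failed; "
                      "refitting with random intercept only", stacklevel=2)
    raise RuntimeError("mixed model could not be fit")


def _extract(res, parameter: str, period: str, data: pd.DataFrame,
             structure: str, converged: bool,
             offset_term: str | None = None) -> TrendFit:
    p = res.pvalues
    b = res.params
    ci = res.conf_int()
    re_var = {k: float(v) for k, v in
              res.cov_re.stack().items()} if hasattr(res, "cov_re") else {}
    fit = TrendFit(
        parameter=parameter, period=period,
        intercept=float(b["Intercept"]), intercept_p=float(p["Intercept"]),
        slope=float(b["day_in_period"]), slope_p=float(p["day_in_period"]),
        slope_ci=(float(ci.loc["day_in_period", 0]),
                  float(ci.loc["day_in_period", 1])),
        age_coef=float(b["age"]), age_p=float(p["age"]),
        bmi_coef=float(b["bmi"]), bmi_p=float(p["bmi"]),
        education_coef=float(b["education"]),
        education_p=float(p["education"]),
        random_structure=structure,
        re_variances=re_var,
        n_subjects=data["subject_id"].nunique(),
        n_nights=len(data),
        converged=converged,
    )
    if offset_term is not None:
        fit.period_offset = float(b[offset_term])
        fit.period_offset_p = float(p[offset_term])
        fit.period_offset_ci = (float(ci.loc[offset_term, 0]),
                                float(ci.loc[offset_term, 1]))
    return fit


def fit_period_trend(cohort: pd.DataFrame, parameter: str, period: str,
                     *, exclude_preterm: bool | None = None) -> TrendFit:
    """Fit the within-period trend model for one parameter.

    Fixed effects: intercept, day_in_period, age, BMI, education.
    Random effects: per-subject intercept and slope on day_in_period.
    Preterm subjects are excluded automatically for the third trimester.
    """
    data = cohort[cohort["period"] == period].copy()
    if exclude_preterm is None:
        exclude_preterm = period == "trimester3"
    if exclude_preterm and "preterm" in data.columns:
        data = data[~data["preterm"].astype(bool)]
    _check_design(data, parameter)
    formula = f"{parameter} ~ day_in_period + age + bmi + education"
    res, structure, converged = _fit_mixed(data, formula, parameter)
    return _extract(res, parameter, period, data, structure, converged)


def compare_periods(cohort: pd.DataFrame, parameter: str,
                    period_a: str, period_b: str) -> TrendFit:
    """Two-period model with a binary period indicator (period_b = 1).

    Time stays anchored to each period's own start (day_in_period), so the
    indicator estimates the level offset of period_b at its period start.
    """
    if period_a == period_b:
        raise ValueError("periods to compare must differ")
    data = cohort[cohort["period"].isin([period_a, period_b])].copy()
    if "trimester3" in (period_a, period_b) and "preterm" in data.columns:
        data = data[~((data["period"] == "trimester3")
                      & data["preterm"].astype(bool))]
    data["period_b"] = (data["period"] == period_b).astype(int)
    _check_design(data, parameter)
    formula = (f"{parameter} ~ day_in_period + period_b + age + bmi "
               "+ education")
    res, structure, converged = _fit_mixed(data, formula, parameter)
    return _extract(res, parameter, f"{period_a} vs {period_b}", data,
                    structure, converged, offset_term="period_b")


def weekly_profile(cohort: pd.DataFrame, parameter: str,
                   period: str | None = None) -> pd.DataFrame:
    """Weekly mean with normal-approximation 95% CI and subject counts.

    One row per week present in the data (ascending, no duplicates):
    mean over subject-nights, mean +/- 1.96 * SE bounds, and the number of
    distinct subjects contributing. Empty weeks are simply absent.
    """
    data = cohort if period is None else cohort[cohort["period"] == period]
    data = data.dropna(subset=[parameter])
    if parameter not in cohort.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    rows = []
    for week, grp in data.groupby("week"):
        vals = grp[parameter].to_numpy(dtype=float)
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 \
            else 0.0
        rows.append({"week": int(week), "mean": mean,
                     "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se,
                     "n_subjects": int(grp["subject_id"].nunique()),
                     "n_nights": int(vals.size)})
    return pd.DataFrame(rows).sort_values("week").reset_index(drop=True)


def fit_all_trends(cohort: pd.DataFrame, parameters: list[str],
                   periods: list[str]) -> pd.DataFrame:
    """Tidy table of per-period fits (rows = period x parameter)."""
    rows = []
    for period in periods:
        for param in parameters:
            try:
                rows.append(fit_period_trend(cohort, param, period).to_row())
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"{param}/{period}: {exc}", stacklevel=2)
    columns = ["parameter", "period", "intercept", "intercept_p", "slope",
               "slope_p", "age_coef", "age_p", "bmi_coef", "bmi_p",
               "education_coef", "education_p", "n_subjects", "n_nights",
               "random_structure"]
    return pd.DataFrame(rows, columns=columns)
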