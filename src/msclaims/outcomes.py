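"""Hospitalization outcomes: classification, annualized rates, comparison.

A stay qualifies as a hospitalization only when its length of stay
exceeds one day — same-day and 1-day stays are treatment-requirement
visits (natalizumab infusion, fingolimod first-dose monitoring) and would
otherwise bias the rate.  Qualifying stays are attributed to the
treatment line whose interval contains the admission date; stays outside
any line are excluded from the rate.

AHR (annualized hospitalization rate) = qualifying events / person-years
at risk in the stratum, pooled over patients.  The 95% CI is the exact
Poisson (Garwood) interval; two rates are compared by the exact
conditional test (given the total event count, the split is binomial with
probability proportional to person-time), with a Wald test on the rate
difference as the fallback for weighted, non-integer event counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .common import DAYS_PER_YEAR, get_logger

log = get_logger(__name__)


@dataclass
class AhrEstimate:
    events: float
    person_years: float
    rate: float
    ci_low: float
    ci_high: float
    stratum: str = ""


@dataclass
class RateComparison:
    rate_a: AhrEstimate
    rate_b: AhrEstimate
    difference: float
    difference_ci: tuple
    percent_reduction: float | None
    p_value: float
    method: str


def classify_hospitalizations(stays: pd.DataFrame, lines: pd.DataFrame
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify inpatient stays and attribute them to treatment lines.

    ``stays`` needs patient_id, admission_date, discharge_date,
    procedure_code, procedure_quantity.  Rows sharing (patient_id,
    admission, discharge) are one stay whose procedure rows are pooled.
    Stays with discharge before admission are rejected with a warning.
    Returns ``(hospitalizations, procedures)``: one row per stay with
    los_days, qualifying (los > 1) and attributed line_number (NaN when
    the admission falls inside no line), and a long procedure frame
    (hosp_id, procedure_code, quantity).
    """
    df = stays.dropna(subset=["patient_id"]).copy()
    bad = df["discharge_date"] < df["admission_date"]
    if bad.any():
        log.warning("rejecting %d stays with discharge before admission",
                    int(bad.sum()))
        df = df[~bad]
    keys = ["patient_id", "admission_date", "discharge_date"]
    grouped = df.groupby(keys, sort=True)
    hosp = grouped.size().rename("n_rows").reset_index()
    hosp.insert(0, "hosp_id", np.arange(len(hosp)))
    hosp["los_days"] = (hosp["discharge_date"] - hosp["admission_date"]).dt.days
    hosp["qualifying"] = hosp["los_days"] > 1

    # attribute by admission-date containment in [line start, line end)
    hosp["line_number"] = np.nan
    hosp["line_drug"] = None
    if len(lines):
        cand = hosp[["hosp_id", "patient_id", "admission_date"]].merge(
            lines[["patient_id", "line_number", "drug_code", "start", "end"]],
            on="patient_id", how="inner")
        inside = ((cand["admission_date"] >= cand["start"])
                  & (cand["admission_date"] < cand["end"]))
        hits = cand[inside].drop_duplicates("hosp_id").set_index("hosp_id")
        hosp = hosp.set_index("hosp_id")
        hosp.loc[hits.index, "line_number"] = hits["line_number"]
        hosp.loc[hits.index, "line_drug"] = hits["drug_code"]
        hosp = hosp.reset_index()

    proc = df.merge(hosp[keys + ["hosp_id"]], on=keys)
    procedures = (proc.groupby(["hosp_id", "procedure_code"], sort=True)
                  ["procedure_quantity"].sum().rename("quantity").reset_index())
    return hosp.drop(columns="n_rows"), procedures


def garwood_ci(events: float, person_years: float,
               alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson (Garwood) CI for a rate from events and person-time."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    low = 0.0 if events <= 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2 / person_years
    high = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2 / person_years
    return float(low), float(high)


def ahr_from_counts(events: float, person_years: float,
                    stratum: str = "") -> AhrEstimate:
    if person_years <= 0:
        raise ValueError(f"zero person-time in stratum '{stratum}'")
    low, high = garwood_ci(events, person_years)
    return AhrEstimate(events=float(events), person_years=float(person_years),
                       rate=float(events) / float(person_years),
                       ci_low=low, ci_high=high, stratum=stratum)


def compute_ahr(hospitalizations: pd.DataFrame, lines: pd.DataFrame,
                line_number: int | None = None,
                patient_ids=None,
                weights: pd.Series | None = None,
                stratum: str = "") -> AhrEstimate:
    """Pooled AHR for a stratum (a line number within a patient subset).

    events = qualifying stays attributed to the selected lines;
    person-years = sum of selected line durations / 365.25.  Optional
    per-patient ``weights`` (IPW) multiply both events and person-time.
    """
    sel_lines = lines
    sel_hosp = hospitalizations[hospitalizations["qualifying"]]
    if line_number is not None:
        sel_lines = sel_lines[sel_lines["line_number"] == line_number]
        sel_hosp = sel_hosp[sel_hosp["line_number"] == line_number]
    if patient_ids is not None:
        ids = set(patient_ids)
        sel_lines = sel_lines[sel_lines["patient_id"].isin(ids)]
        sel_hosp = sel_hosp[sel_hosp["patient_id"].isin(ids)]
    if weights is None:
        w_line = np.ones(len(sel_lines))
        w_hosp = np.ones(len(sel_hosp))
    else:
        w_line = weights.reindex(sel_lines["patient_id"]).to_numpy()
        w_hosp = weights.reindex(sel_hosp["patient_id"]).to_numpy()
    days = (sel_lines["end"] - sel_lines["start"]).dt.days.to_numpy()
    person_years = float((days * w_line).sum()) / DAYS_PER_YEAR
    events = float(w_hosp.sum())
    return ahr_from_counts(events, person_years, stratum=stratum)


def rate_difference(rate_a: float, rate_b: float) -> float:
    """Difference of two annualized rates (a minus b)."""
    return rate_a - rate_b


def percent_reduction(rate_a: float, rate_b: float) -> float | None:
    """100 x (a - b) / a; undefined (None) when the reference rate is 0."""
    if rate_a == 0:
        return None
    return 100.0 * (rate_a - rate_b) / rate_a


def _exact_conditional_p(k_a: float, t_a: float, k_b: float, t_b: float) -> float:
    n = int(round(k_a + k_b))
    if n == 0:
        return 1.0
    return float(stats.binomtest(int(round(k_a)), n, t_a / (t_a + t_b)).pvalue)


def compare_rates(a: AhrEstimate, b: AhrEstimate,
                  method: str = "auto") -> RateComparison:
    """Compare two AHRs: difference, Wald CI, percent reduction, p-value.

    method "exact": conditional binomial test on the event split (the
    classical two-sample Poisson test); "wald": normal test on the rate
    difference; "auto": exact when both event counts are integral, else
    wald (weighted analyses produce non-integer events).
    """
    diff = rate_difference(a.rate, b.rate)
    var = a.rate / a.person_years + b.rate / b.person_years
    se = np.sqrt(var)
    ci = (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se)
    reduction = percent_reduction(a.rate, b.rate)
    if reduction is None:
        log.warning("percent reduction undefined: reference rate is zero")

    integral = (abs(a.events - round(a.events)) < 1e-9
                and abs(b.events - round(b.events)) < 1e-9)
    if method == "auto":
        method = "exact" if integral else "wald"
    if method == "exact":
        if not integral:
            raise ValueError("exact conditional test requires integer event counts")
        p = _exact_conditional_p(a.events, a.person_years, b.events, b.person_years)
    elif method == "wald":
        if se == 0:
            p = 1.0
        else:
            z = diff / se
            p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method '{method}'")
    return RateComparison(rate_a=a, rate_b=b, difference=diff,
                          difference_ci=ci, percent_reduction=reduction,
                          p_value=p, method=method)


def procedure_profile(hospitalizations: pd.DataFrame,
                      procedures: pd.DataFrame) -> pd.DataFrame:
    """Per-code totals and per-hospitalized-patient distributions.

    Percentages are over all inpatient procedure records; the
    per-patient statistics (mean, SD, median, min, max) count, for every
    hospitalized patient, how often the code was billed (zero when never),
    mirroring a procedure-frequency table.
    """
    qual = hospitalizations[hospitalizations["qualifying"]]
    proc = procedures[procedures["hosp_id"].isin(qual["hosp_id"])]
    merged = proc.merge(qual[["hosp_id", "patient_id"]], on="hosp_id")
    total_all = merged["quantity"].sum()
    patients = qual["patient_id"].unique()
    rows = []
    for code, grp in merged.groupby("procedure_code", sort=True):
        per_patient = (grp.groupby("patient_id")["quantity"].sum()
                       .reindex(patients).fillna(0.0))
        rows.append({
            "procedure_code": code,
            "total": int(grp["quantity"].sum()),
            "pct": 100.0 * grp["quantity"].sum() / total_all if total_all else np.nan,
            "per_patient_mean": per_patient.mean(),
            "per_patient_sd": per_patient.std(ddof=1),
            "per_patient_median": per_patient.median(),
            "per_patient_min": per_patient.min(),
            "per_patient_max": per_patient.max(),
        })
    out = pd.DataFrame(rows).sort_values("total", ascending=False).reset_index(drop=True)
    return out


def stratum_utilization(hospitalizations: pd.DataFrame,
                        procedures: pd.DataFrame,
                        strata: pd.Series) -> pd.DataFrame:
    """Hospital-days and procedure counts per hospitalized patient by stratum.

    ``strata`` maps patient_id -> stratum label (e.g. second-line drug).
    Summarizes, over hospitalized patients in each stratum, total days of
    hospitalization and total procedure records (mean, SD, median,
    min-max).
    """
    qual = hospitalizations[hospitalizations["qualifying"]].copy()
    qual["stratum"] = strata.reindex(qual["patient_id"]).to_numpy()
    qual = qual.dropna(subset=["stratum"])
    nproc = (procedures.groupby("hosp_id")["quantity"].sum()
             .reindex(qual["hosp_id"]).fillna(0).to_numpy())
    qual["n_procedures"] = nproc
    rows = []
    for label, grp in qual.groupby("stratum", sort=True):
        per_pat = grp.groupby("patient_id").agg(
            days=("los_days", "sum"), procs=("n_procedures", "sum"))
        rows.append({
            "stratum": label,
            "n_hospitalized": len(per_pat),
            "procedures_mean": per_pat["procs"].mean(),
            "procedures_sd": per_pat["procs"].std(ddof=1),
            "procedures_median": per_pat["procs"].median(),
            "procedures_min": per_pat["procs"].min(),
            "procedures_max": per_pat["procs"].max(),
            "days_mean": per_pat["days"].mean(),
            "days_sd": per_pat["days"].std(ddof=1),
            "days_median": per_pat["days"].median(),
            "days_min": per_pat["days"].min(),
            "days_max": per_pat["days"].max(),
        })
    return pd.DataFrame(rows)
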