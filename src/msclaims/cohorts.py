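"""Eligibility screening and cohort construction.

Cohort 1 (treatment-pattern / hospitalization-profile population):
patients with at least one MS drug-dispensing claim (ICD-10 G35), aged
>= 18 at the first MS claim, first treatment started inside the study
window (patients already on therapy before the window are excluded),
first-line drug among the platform therapies, at least 12 months of
follow-up from first treatment to the last observed claim, and at least
two lines of therapy.  Criteria are applied in that fixed order and the
first failed criterion is recorded, so attrition tables are reproducible.

Cohort 2 (the natalizumab-vs-fingolimod comparison) is the subset of
cohort 1 whose second-line drug is natalizumab or fingolimod; the arm is
the second-line drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .common import (ALL_DRUGS, DAYS_PER_MONTH, DAYS_PER_YEAR, FINGOLIMOD,
                     NATALIZUMAB, PLATFORM_DRUGS, get_logger)

log = get_logger(__name__)

CRITERIA = ("has_ms_claim", "age_ge_18", "start_in_window",
            "platform_first_line", "followup_ge_12m", "two_or_more_lines")

CONTINUOUS_COVARIATES = ("age_at_first_claim", "time_to_treatment_months",
                         "time_in_line1_years")
CATEGORICAL_COVARIATES = ("sex", "region", "line1_drug")


@dataclass
class StudyWindow:
    start: date = date(2013, 1, 1)
    end: date = date(2017, 12, 31)


def build_eligibility(patients: pd.DataFrame, out_claims: pd.DataFrame,
                      inp_claims: pd.DataFrame, lines: pd.DataFrame,
                      window: StudyWindow | None = None,
                      platform_drugs: tuple = PLATFORM_DRUGS) -> pd.DataFrame:
    """One EligibilityRecord row per linked patient.

    ``out_claims``/``inp_claims`` must carry patient_id (see
    ``linkage.claims_with_patient_ids``); first MS claim = earliest
    outpatient claim with the MS diagnosis; first treatment = start of
    line 1; follow-up runs from first treatment to the last observed
    claim in either file.
    """
    window = window or StudyWindow()
    idx = patients["patient_id"].to_numpy()
    rec = pd.DataFrame({"patient_id": idx}).set_index("patient_id")

    grouped_out = out_claims.dropna(subset=["patient_id"]).groupby("patient_id")
    rec["first_claim_date"] = grouped_out["dispense_date"].min()
    last_out = grouped_out["dispense_date"].max()
    drug_claims = out_claims[out_claims["drug_code"].isin(ALL_DRUGS)]
    rec["n_drug_claims"] = drug_claims.groupby("patient_id").size()
    rec["n_drug_claims"] = rec["n_drug_claims"].fillna(0).astype(int)

    last_inp = (inp_claims.dropna(subset=["patient_id"])
                .groupby("patient_id")["discharge_date"].max()
                if len(inp_claims) else pd.Series(dtype="datetime64[ns]"))
    rec["last_claim_date"] = pd.concat(
        [last_out, last_inp], axis=1).max(axis=1)

    line_info = lines.sort_values(["patient_id", "line_number"])
    first_lines = line_info[line_info["line_number"] == 1].set_index("patient_id")
    second_lines = line_info[line_info["line_number"] == 2].set_index("patient_id")
    rec["first_treatment_date"] = first_lines["start"]
    rec["line1_drug"] = first_lines["drug_code"]
    rec["line1_end"] = first_lines["end"]
    rec["line2_drug"] = second_lines["drug_code"]
    rec["n_lines"] = lines.groupby("patient_id")["line_number"].max()
    rec["n_lines"] = rec["n_lines"].fillna(0).astype(int)

    dob = patients.set_index("patient_id")["dob"]
    rec["age_at_first_claim"] = ((rec["first_claim_date"] - dob).dt.days
                                 / DAYS_PER_YEAR)
    rec["followup_months"] = ((rec["last_claim_date"] - rec["first_treatment_date"])
                              .dt.days / DAYS_PER_MONTH)

    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.end)
    rec["has_ms_claim"] = rec["n_drug_claims"] > 0
    rec["age_ge_18"] = rec["age_at_first_claim"] >= 18.0
    rec["start_in_window"] = (rec["first_treatment_date"].notna()
                              & (rec["first_treatment_date"] >= start)
                              & (rec["first_treatment_date"] <= end))
    rec["platform_first_line"] = rec["line1_drug"].isin(platform_drugs)
    rec["followup_ge_12m"] = rec["followup_months"] >= 12.0
    rec["two_or_more_lines"] = rec["n_lines"] >= 2

    flags = rec[list(CRITERIA)].fillna(False).astype(bool)
    rec[list(CRITERIA)] = flags
    rec["eligible_cohort1"] = flags.all(axis=1)
    first_fail = flags.apply(
        lambda row: next((c for c in CRITERIA if not row[c]), None), axis=1)
    rec["exclusion_reason"] = first_fail
    return rec.reset_index()


def evaluate_cohort1(eligibility: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Cohort-1 assignment plus an attrition funnel.

    Attrition counts each patient against the first criterion failed, in
    the fixed criterion order; screened = sum(excluded) + cohort-1 size.
    """
    assignment = eligibility[["patient_id"]].copy()
    assignment["in_cohort1"] = eligibility["eligible_cohort1"].to_numpy()
    attrition = {"screened": int(len(eligibility))}
    for c in CRITERIA:
        attrition[f"excluded_{c}"] = int((eligibility["exclusion_reason"] == c).sum())
    attrition["cohort1"] = int(assignment["in_cohort1"].sum())
    return assignment, attrition


def evaluate_cohort2(assignment: pd.DataFrame,
                     eligibility: pd.DataFrame) -> pd.DataFrame:
    """Cohort 2: cohort-1 members whose line-2 drug is NAT or FINGO."""
    out = assignment.merge(eligibility[["patient_id", "line2_drug"]], on="patient_id")
    arm = np.select(
        [out["in_cohort1"] & (out["line2_drug"] == NATALIZUMAB),
         out["in_cohort1"] & (out["line2_drug"] == FINGOLIMOD)],
        [NATALIZUMAB, FINGOLIMOD], default="none")
    out["cohort2_arm"] = arm
    out["in_cohort2"] = arm != "none"
    return out[["patient_id", "in_cohort1", "in_cohort2", "cohort2_arm"]]


def build_covariates(eligibility: pd.DataFrame, patients: pd.DataFrame,
                     lines: pd.DataFrame) -> pd.DataFrame:
    """Adjustment covariates per patient (cohort-2 oriented).

    age at first MS claim (years), sex, region, time from first MS claim
    to first treatment (months), first-line drug, time in first line
    (years).
    """
    cov = eligibility.set_index("patient_id")[
        ["age_at_first_claim", "line1_drug", "first_claim_date",
         "first_treatment_date", "line1_end", "line2_drug"]].copy()
    cov["time_to_treatment_months"] = (
        (cov["first_treatment_date"] - cov["first_claim_date"]).dt.days
        / DAYS_PER_MONTH)
    cov["time_in_line1_years"] = (
        (cov["line1_end"] - cov["first_treatment_date"]).dt.days / DAYS_PER_YEAR)
    demo = patients.set_index("patient_id")[["sex", "region"]]
    cov = cov.join(demo)
    return cov.drop(columns=["first_claim_date", "first_treatment_date",
                             "line1_end"]).reset_index()


def baseline_table(covariates: pd.DataFrame, arm: pd.Series,
                   weights: pd.Series | None = None,
                   paper_literal_tests: bool = False) -> pd.DataFrame:
    """Per-arm covariate summary with between-arm tests.

    Continuous covariates: mean (SD) per arm and Welch t-test; categorical
    covariates: n (%) per level and a chi-square test on the contingency
    table.  ``paper_literal_tests`` replaces the chi-square with t-tests
    on the per-level indicator variables (reported per level).  With
    weights, summaries are weight-based and tests are suppressed.  An arm
    with fewer than two patients suppresses tests with a notice.
    """
    df = covariates.copy()
    df["_arm"] = arm.to_numpy() if isinstance(arm, pd.Series) else arm
    df["_w"] = (weights.to_numpy() if isinstance(weights, pd.Series)
                else (weights if weights is not None else np.ones(len(df))))
    arms = sorted(df["_arm"].unique())
    tests_ok = (weights is None
                and all((df["_arm"] == a).sum() >= 2 for a in arms)
                and len(arms) == 2)
    if not tests_ok:
        log.info("baseline_table: between-arm tests suppressed "
                 "(weighted summary or an arm with < 2 patients)")
    rows = []
    for covar in CONTINUOUS_COVARIATES:
        entry = {"covariate": covar, "level": ""}
        groups = []
        for a in arms:
            sub = df[df["_arm"] == a]
            m = np.average(sub[covar], weights=sub["_w"])
            v = np.average((sub[covar] - m) ** 2, weights=sub["_w"])
            n_eff = len(sub)
            entry[f"mean_{a}"] = m
            entry[f"sd_{a}"] = np.sqrt(v * n_eff / max(n_eff - 1, 1))
            groups.append(sub[covar].to_numpy())
        if tests_ok:
            if np.ptp(np.concatenate(groups)) == 0:
                entry["p_value"] = 1.0
            else:
                entry["p_value"] = float(stats.ttest_ind(
                    groups[0], groups[1], equal_var=False).pvalue)
        else:
            entry["p_value"] = np.nan
        rows.append(entry)
    for covar in CATEGORICAL_COVARIATES:
        levels = sorted(df[covar].dropna().unique())
        table = np.zeros((len(levels), len(arms)))
        for j, a in enumerate(arms):
            sub = df[df["_arm"] == a]
            for i, lv in enumerate(levels):
                table[i, j] = sub.loc[sub[covar] == lv, "_w"].sum()
        p_chi = np.nan
        if tests_ok and not paper_literal_tests and table.shape[0] > 1:
            nonzero = table.sum(axis=1) > 0
            if nonzero.sum() > 1:
                p_chi = float(stats.chi2_contingency(table[nonzero]).pvalue)
        for i, lv in enumerate(levels):
            entry = {"covariate": covar, "level": str(lv)}
            for j, a in enumerate(arms):
                tot = table[:, j].sum()
                entry[f"n_{a}"] = table[i, j]
                entry[f"pct_{a}"] = 100.0 * table[i, j] / tot if tot else np.nan
            if tests_ok and paper_literal_tests:
                ind = [(df.loc[df["_arm"] == a, covar] == lv).astype(float).to_numpy()
                       for a in arms]
                if np.ptp(np.concatenate(ind)) == 0:
                    entry["p_value"] = 1.0
                else:
                    entry["p_value"] = float(stats.ttest_ind(
                        ind[0], ind[1], equal_var=False).pvalue)
            else:
                entry["p_value"] = p_chi if i == 0 else np.nan
            rows.append(entry)
    return pd.DataFrame(rows)
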