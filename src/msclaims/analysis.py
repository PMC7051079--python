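"""Cohort-2 comparison: unmatched, PS-matched and IPW rate analyses.

Works on a per-patient analysis frame (one row per cohort-2 patient with
covariates, treatment arm and first/second-line event counts and
person-years), so the same machinery serves the full claims pipeline and
ground-truth-based simulation studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import adjustment, outcomes
from .common import (DAYS_PER_MONTH, DAYS_PER_YEAR, FINGOLIMOD, NATALIZUMAB,
                     PLATFORM_DRUGS, get_logger)

log = get_logger(__name__)

FRAME_COLUMNS = [
    "patient_id", "treatment", "age_at_first_claim", "sex", "region",
    "time_to_treatment_months", "line1_drug", "time_in_line1_years",
    "events_line1", "py_line1", "events_line2", "py_line2",
]


def patient_line_counts(hospitalizations: pd.DataFrame, lines: pd.DataFrame,
                        line_number: int) -> pd.DataFrame:
    """Qualifying events and person-years per patient for one line."""
    sel = lines[lines["line_number"] == line_number]
    py = ((sel["end"] - sel["start"]).dt.days / DAYS_PER_YEAR)
    py = py.groupby(sel["patient_id"].to_numpy()).sum()
    qual = hospitalizations[(hospitalizations["qualifying"])
                            & (hospitalizations["line_number"] == line_number)]
    ev = qual.groupby("patient_id").size()
    out = pd.DataFrame({"py": py})
    out["events"] = ev.reindex(out.index).fillna(0).astype(int)
    out.index.name = "patient_id"
    return out.reset_index()


def build_analysis_frame(covariates: pd.DataFrame, cohort2: pd.DataFrame,
                         hospitalizations: pd.DataFrame,
                         lines: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-patient cohort-2 analysis frame from pipeline stages."""
    members = cohort2[cohort2["in_cohort2"]]
    frame = members[["patient_id", "cohort2_arm"]].merge(covariates, on="patient_id")
    frame["treatment"] = (frame["cohort2_arm"] == NATALIZUMAB).astype(int)
    for ln in (1, 2):
        counts = patient_line_counts(hospitalizations, lines, ln)
        counts = counts.rename(columns={"events": f"events_line{ln}",
                                        "py": f"py_line{ln}"})
        frame = frame.merge(counts, on="patient_id", how="left")
        frame[f"events_line{ln}"] = frame[f"events_line{ln}"].fillna(0)
        frame[f"py_line{ln}"] = frame[f"py_line{ln}"].fillna(0.0)
    return frame[FRAME_COLUMNS]


def _weighted_ahr(frame: pd.DataFrame, line: int, stratum: str,
                  weights: pd.Series | None = None) -> outcomes.AhrEstimate:
    w = (weights.reindex(frame["patient_id"]).to_numpy()
         if weights is not None else np.ones(len(frame)))
    events = float((frame[f"events_line{line}"].to_numpy() * w).sum())
    py = float((frame[f"py_line{line}"].to_numpy() * w).sum())
    return outcomes.ahr_from_counts(events, py, stratum=stratum)


def _arm_rows(frame: pd.DataFrame, analysis: str,
              weights: pd.Series | None = None) -> list[dict]:
    """Table-3-style rows for one analysis: per arm line-1 AHR, line-2 AHR,
    within-arm difference (first minus second line) and the between-arm
    second-line comparison (fingolimod minus natalizumab)."""
    rows = []
    arm_line2 = {}
    for arm, code in ((NATALIZUMAB, 1), (FINGOLIMOD, 0)):
        sub = frame[frame["treatment"] == code]
        if sub.empty:
            continue
        a1 = _weighted_ahr(sub, 1, f"{arm}/line1", weights)
        a2 = _weighted_ahr(sub, 2, f"{arm}/line2", weights)
        cmp_ = outcomes.compare_rates(a1, a2)
        arm_line2[arm] = a2
        for est, label in ((a1, "platform_first_line"), (a2, "second_line")):
            rows.append({"analysis": analysis, "arm": arm, "measure": label,
                         "events": est.events, "person_years": est.person_years,
                         "rate": est.rate, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "difference": np.nan,
                         "percent_reduction": np.nan, "p_value": np.nan})
        rows.append({"analysis": analysis, "arm": arm,
                     "measure": "difference_line1_minus_line2",
                     "events": np.nan, "person_years": np.nan,
                     "rate": np.nan,
                     "ci_low": cmp_.difference_ci[0],
                     "ci_high": cmp_.difference_ci[1],
                     "difference": cmp_.difference,
                     "percent_reduction": cmp_.percent_reduction,
                     "p_value": cmp_.p_value})
    if len(arm_line2) == 2:
        cmp2 = outcomes.compare_rates(arm_line2[FINGOLIMOD], arm_line2[NATALIZUMAB])
        rows.append({"analysis": analysis, "arm": "between_arms",
                     "measure": "second_line_fingolimod_minus_natalizumab",
                     "events": np.nan, "person_years": np.nan, "rate": np.nan,
                     "ci_low": cmp2.difference_ci[0],
                     "ci_high": cmp2.difference_ci[1],
                     "difference": cmp2.difference,
                     "percent_reduction": np.nan, "p_value": cmp2.p_value})
    return rows


def cohort2_analysis(frame: pd.DataFrame, seed: int = 0,
                     caliper: float | None = adjustment.DEFAULT_CALIPER,
                     ipw_mode: str = "standard", stabilized: bool = False,
                     truncate_percentile: float | None = 99.0,
                     penalized: bool = False) -> dict:
    """Run the three cohort-2 analyses and return rates plus artifacts.

    Returns a dict with ``table`` (Table-3-shaped long frame over
    unmatched / matched / ipw analyses), ``ps`` (records with fitted PS
    and weights), ``matched`` (the MatchedCohort), ``balance_matched``
    and ``balance_ipw`` reports, and ``ps_params``.
    """
    rows = _arm_rows(frame, "unmatched")
    ps_frame, params = adjustment.fit_propensity(frame, penalized=penalized)
    matched = adjustment.match_nearest(ps_frame, caliper=caliper, seed=seed)
    weighted = adjustment.compute_ipw(ps_frame, mode=ipw_mode,
                                      stabilized=stabilized,
                                      truncate_percentile=truncate_percentile)
    if len(matched.pairs):
        msub = frame[frame["patient_id"].isin(matched.patient_ids)]
        rows += _arm_rows(msub, "matched")
    w = weighted.set_index("patient_id")["weight"]
    rows += _arm_rows(frame, "ipw", weights=w)
    table = pd.DataFrame(rows)
    bal_m = adjustment.balance_report(ps_frame, matched=matched)
    bal_w = adjustment.balance_report(ps_frame, weighted=weighted)
    return {"table": table, "ps": weighted, "matched": matched,
            "balance_matched": bal_m, "balance_ipw": bal_w,
            "ps_params": params}


# ---------------------------------------------------------------------------
# ground-truth shortcuts for simulation studies
# ---------------------------------------------------------------------------

def truth_analysis_frame(truth) -> pd.DataFrame:
    """Cohort-2 analysis frame straight from the generator's ground truth.

    Applies the eligibility rules to the true tables (no linkage or
    episode reconstruction), returning the frame plus the true
    confounder multiplier for estimand computation.
    """
    cfg = truth.config
    pat = truth.patients.set_index("patient_id")
    lines = truth.lines
    ln1 = lines[lines["line_number"] == 1].set_index("patient_id")
    ln2 = lines[lines["line_number"] == 2].set_index("patient_id")
    last_end = lines.groupby("patient_id")["end"].max()

    f = pd.DataFrame(index=pat.index)
    f["age_at_first_claim"] = pat["age_at_first_claim"]
    f["sex"] = pat["sex"]
    f["region"] = pat["region"]
    f["time_to_treatment_months"] = ((pat["first_treatment"] - pat["first_ms_claim"])
                                     .dt.days / DAYS_PER_MONTH)
    f["line1_drug"] = ln1["drug"]
    f["time_in_line1_years"] = ((ln1["end"] - ln1["start"]).dt.days / DAYS_PER_YEAR)
    f["line2_drug"] = ln2["drug"]
    f["followup_months"] = ((last_end - pat["first_treatment"]).dt.days
                            / DAYS_PER_MONTH)
    f["confounder_multiplier"] = pat["confounder_multiplier"]

    eligible = (
        (f["age_at_first_claim"] >= 18)
        & (pat["first_treatment"] >= pd.Timestamp(cfg.study_start))
        & (pat["first_treatment"] <= pd.Timestamp(cfg.study_end))
        & f["line1_drug"].isin(PLATFORM_DRUGS)
        & (f["followup_months"] >= 12)
        & f["line2_drug"].isin([NATALIZUMAB, FINGOLIMOD])
    )
    f = f[eligible.fillna(False)].copy()
    f["treatment"] = (f["line2_drug"] == NATALIZUMAB).astype(int)

    hosp = truth.hospitalizations.assign(qualifying=True)
    for ln in (1, 2):
        sel = lines[lines["line_number"] == ln]
        py = sel.set_index("patient_id")["person_years"]
        ev = (hosp[hosp["line_number"] == ln].groupby("patient_id").size())
        f[f"py_line{ln}"] = py.reindex(f.index).fillna(0.0)
        f[f"events_line{ln}"] = ev.reindex(f.index).fillna(0).astype(int)
    f.index.name = "patient_id"
    f = f.reset_index()
    return f


def true_rate_difference(frame: pd.DataFrame, config,
                         patient_ids=None) -> float:
    """True second-line rate difference (fingolimod minus natalizumab)
    for a given population, person-time weighted over its members.

    Uses the counterfactual rates base x ratio_drug x multiplier, so the
    same population quantity exists for either arm assignment.
    """
    sub = frame if patient_ids is None else frame[frame["patient_id"].isin(set(patient_ids))]
    t = sub["py_line2"].to_numpy()
    m = sub["confounder_multiplier"].to_numpy()
    if t.sum() <= 0:
        return np.nan
    mean_tm = (t * m).sum() / t.sum()
    base = config.true_rate_line1
    return base * (config.true_rate_ratio_fingolimod
                   - config.true_rate_ratio_natalizumab) * mean_tm


def estimate_rate_differences(frame: pd.DataFrame, seed: int = 0,
                              truncate_percentile: float | None = 99.0) -> dict:
    """Second-line fingolimod-minus-natalizumab rate-difference estimates
    under the unadjusted, PS-matched and IPW analyses (point estimates
    only; used by simulation studies)."""
    def diff(sub, weights=None):
        nat = sub[sub["treatment"] == 1]
        fin = sub[sub["treatment"] == 0]
        a = _weighted_ahr(fin, 2, "f", weights)
        b = _weighted_ahr(nat, 2, "n", weights)
        return a.rate - b.rate

    out = {"unadjusted": diff(frame)}
    ps_frame, _ = adjustment.fit_propensity(frame)
    matched = adjustment.match_nearest(ps_frame, seed=seed)
    if len(matched.pairs):
        out["matched"] = diff(frame[frame["patient_id"].isin(matched.patient_ids)])
        out["matched_ids"] = matched.patient_ids
    weighted = adjustment.compute_ipw(ps_frame,
                                      truncate_percentile=truncate_percentile)
    out["ipw"] = diff(frame, weighted.set_index("patient_id")["weight"])
    return out
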