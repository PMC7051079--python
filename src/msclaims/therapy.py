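"""Treatment episodes, lines of therapy and switching patterns.

Dispensing claims are chained into same-drug episodes (a claim covers
``coverage_days`` of supply; consecutive same-drug claims whose gap is at
most coverage + grace belong to one episode; episode end = last claim +
coverage).  Overlapping episodes of different drugs are truncated at the
later episode's start (MS disease-modifying therapies are not
co-administered; the switch date is the first claim of the new drug).
Lines of therapy then increment at every drug change between consecutive
episodes — returning to a previously used drug still starts a new line —
while consecutive same-drug episodes separated only by a gap merge into
one line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .common import ALL_DRUGS, DAYS_PER_MONTH, get_logger

log = get_logger(__name__)

DEFAULT_COVERAGE_DAYS = 30
DEFAULT_GRACE_DAYS = 60


def build_episodes(claims: pd.DataFrame,
                   grace_days: int = DEFAULT_GRACE_DAYS,
                   coverage_days: int = DEFAULT_COVERAGE_DAYS,
                   known_drugs: tuple = ALL_DRUGS) -> pd.DataFrame:
    """Chain dispensing claims into treatment episodes.

    ``claims`` needs columns patient_id, dispense_date, drug_code.  Claims
    with a drug code outside ``known_drugs`` (diagnostic work-up rows,
    typos) are skipped with a warning.  Returns one row per episode:
    patient_id, drug_code, start, end, n_claims, non-overlapping within
    patient after truncation.
    """
    df = claims[["patient_id", "dispense_date", "drug_code"]].dropna(subset=["patient_id"])
    unknown = ~df["drug_code"].isin(known_drugs)
    if unknown.any():
        skipped = df.loc[unknown, "drug_code"].value_counts()
        log.warning("skipping %d claims with unknown drug codes: %s",
                    int(unknown.sum()), dict(skipped))
        df = df[~unknown]
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "drug_code", "start", "end", "n_claims"])

    max_gap = coverage_days + grace_days
    df = df.sort_values(["patient_id", "drug_code", "dispense_date"], kind="mergesort")
    # new episode whenever patient/drug changes or the gap exceeds the rule
    gap = df["dispense_date"].diff().dt.days
    new = ((df["patient_id"] != df["patient_id"].shift())
           | (df["drug_code"] != df["drug_code"].shift())
           | (gap > max_gap))
    df = df.assign(_episode=new.cumsum())
    eps = df.groupby("_episode").agg(
        patient_id=("patient_id", "first"),
        drug_code=("drug_code", "first"),
        start=("dispense_date", "min"),
        end=("dispense_date", "max"),
        n_claims=("dispense_date", "size"),
    ).reset_index(drop=True)
    eps["end"] = eps["end"] + pd.Timedelta(days=coverage_days)

    # resolve cross-drug overlaps: truncate the earlier episode at the
    # later episode's start (may leave a zero-length episode)
    eps = eps.sort_values(["patient_id", "start", "end"], kind="mergesort").reset_index(drop=True)
    next_start = eps.groupby("patient_id")["start"].shift(-1)
    truncate = next_start.notna() & (next_start < eps["end"])
    eps.loc[truncate, "end"] = next_start[truncate]
    eps["end"] = eps[["start", "end"]].max(axis=1)
    return eps


def assign_lines(episodes: pd.DataFrame) -> pd.DataFrame:
    """Number lines of therapy from ordered episodes.

    A new line begins when the drug changes between consecutive episodes
    (re-use of an earlier drug included); consecutive same-drug episodes
    merge into one line spanning both.  duration_months uses 30.4375
    days/month.
    """
    if episodes.empty:
        return pd.DataFrame(columns=["patient_id", "line_number", "drug_code",
                                     "start", "end", "duration_months"])
    eps = episodes.sort_values(["patient_id", "start"], kind="mergesort")
    new_line = ((eps["patient_id"] != eps["patient_id"].shift())
                | (eps["drug_code"] != eps["drug_code"].shift()))
    eps = eps.assign(_line=new_line.cumsum())
    lines = eps.groupby("_line").agg(
        patient_id=("patient_id", "first"),
        drug_code=("drug_code", "first"),
        start=("start", "min"),
        end=("end", "max"),
    ).reset_index(drop=True)
    lines["line_number"] = lines.groupby("patient_id").cumcount() + 1
    lines["duration_months"] = (lines["end"] - lines["start"]).dt.days / DAYS_PER_MONTH
    return lines[["patient_id", "line_number", "drug_code", "start", "end",
                  "duration_months"]]


def summarize_patterns(lines: pd.DataFrame, max_line: int = 4) -> pd.DataFrame:
    """Per-line drug frequencies and duration summaries.

    One row per (line_number, drug): n, pct (of patients in that line),
    and duration in months (mean, sd, median, min, max).
    """
    rows = []
    for ln in range(1, max_line + 1):
        sub = lines[lines["line_number"] == ln]
        total = len(sub)
        if total == 0:
            continue
        for drug, grp in sub.groupby("drug_code", sort=True):
            d = grp["duration_months"]
            rows.append({
                "line_number": ln, "drug_code": drug, "n": len(grp),
                "pct": 100.0 * len(grp) / total,
                "duration_mean": d.mean(), "duration_sd": d.std(ddof=1),
                "duration_median": d.median(),
                "duration_min": d.min(), "duration_max": d.max(),
            })
    return pd.DataFrame(rows)


def switch_matrix(lines: pd.DataFrame, from_line: int) -> pd.DataFrame:
    """Transition counts and row-percentages drug(line k) -> drug(line k+1).

    Only patients holding both lines contribute; an empty stratum yields
    an empty matrix.  Returns a long frame: from_drug, to_drug, n, row_pct.
    """
    a = lines[lines["line_number"] == from_line][["patient_id", "drug_code"]]
    b = lines[lines["line_number"] == from_line + 1][["patient_id", "drug_code"]]
    merged = a.merge(b, on="patient_id", suffixes=("_from", "_to"))
    if merged.empty:
        return pd.DataFrame(columns=["from_drug", "to_drug", "n", "row_pct"])
    counts = (merged.groupby(["drug_code_from", "drug_code_to"], sort=True)
              .size().rename("n").reset_index())
    counts.columns = ["from_drug", "to_drug", "n"]
    totals = counts.groupby("from_drug")["n"].transform("sum")
    counts["row_pct"] = 100.0 * counts["n"] / totals
    return counts


def line_sequences(lines: pd.DataFrame) -> pd.Series:
    """Ordered tuple of drugs per patient (for ground-truth comparison)."""
    ordered = lines.sort_values(["patient_id", "line_number"], kind="mergesort")
    return ordered.groupby("patient_id")["drug_code"].agg(tuple)
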