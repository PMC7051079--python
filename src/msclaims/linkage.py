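"""Probabilistic record linkage between the two claim files.

The outpatient and inpatient extracts share no patient identifier, only
noisy quasi-identifiers (date of birth, ZIP, ICD-10, sex, region).  Rows
are first collapsed per file pseudo-ID into one record with majority-vote
consensus keys; candidate cross-file pairs are enumerated within blocks;
each pair is scored with the Fellegi-Sunter log-likelihood-ratio sum
(log2(m/u) on field agreement, log2((1-m)/(1-u)) on disagreement, 0 when
either side is missing); pairs above the threshold are accepted greedily
in descending score under a one-to-one constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .common import ConfigError, EmptyInputError, get_logger

log = get_logger(__name__)

KEY_FIELDS = ("dob", "zip", "icd10")
AUX_FIELDS = ("sex", "region")


@dataclass
class LinkageModel:
    """Per-field m/u probabilities, acceptance threshold and blocking.

    m: P(field agrees | records are the same patient);
    u: P(field agrees | records are different patients).
    A pair is accepted when its total log2 likelihood-ratio score is
    strictly greater than ``threshold`` (default 0: posterior odds must
    favour a match).  ``blocking`` is a list of field subsets; candidate
    pairs are the union over subsets of exact-agreement joins.
    ``zip_prefix`` means the first 4 ZIP digits.
    """

    m: dict = field(default_factory=lambda: {f: 0.95 for f in KEY_FIELDS + AUX_FIELDS})
    u: dict = field(default_factory=dict)  # filled empirically if absent
    threshold: float = 0.0
    blocking: list = field(default_factory=lambda: [("icd10", "zip_prefix"), ("dob",)])
    one_to_one: bool = True

    def validate(self) -> None:
        for f, mv in self.m.items():
            uv = self.u.get(f)
            if uv is None:
                continue
            if not (0.0 < uv < mv < 1.0):
                raise ConfigError(f"linkage field '{f}': need 0 < u < m < 1 "
                                  f"(got m={mv}, u={uv})")
        if not np.isfinite(self.threshold):
            raise ConfigError("threshold must be finite")


def score_pair(a: dict, b: dict, model: LinkageModel) -> float:
    """Fellegi-Sunter log2 likelihood-ratio score for one record pair.

    Additive over fields; a field missing on either side contributes 0;
    an uninformative field (m == u) contributes 0 whatever the data.
    """
    score = 0.0
    for f, m in model.m.items():
        u = model.u.get(f)
        if u is None:
            continue
        va, vb = a.get(f), b.get(f)
        if _missing(va) or _missing(vb):
            continue
        if va == vb:
            score += np.log2(m / u)
        else:
            score += np.log2((1.0 - m) / (1.0 - u))
    return float(score)


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == "" or v is pd.NaT


def _mode(series: pd.Series):
    s = series[~series.isin(["", None]) & series.notna()]
    if s.empty:
        return None
    counts = s.value_counts()
    return counts.index[0]  # value_counts is count-desc, first-seen stable


def aggregate_records(claims: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw claim rows to one record per pseudo_id.

    Consensus dob/zip/sex/region/icd10 by majority vote over member rows
    (corrupted fields are outvoted when a patient has several claims).
    """
    if claims.empty:
        raise EmptyInputError("claim stream is empty")
    fields = [f for f in KEY_FIELDS + AUX_FIELDS if f in claims.columns]
    grouped = claims.groupby("pseudo_id", sort=True)
    rec = grouped[fields].agg(_mode)
    rec["n_rows"] = grouped.size()
    rec = rec.reset_index()
    rec["zip_prefix"] = rec["zip"].astype(str).str[:4].where(rec["zip"].notna(), None)
    return rec


def estimate_u(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict:
    """u-probabilities from empirical value frequencies.

    P(two random records from opposite files agree on the field)
    = sum over values of freq_a * freq_b, clipped away from 0 and 1.
    """
    u = {}
    for f in KEY_FIELDS + AUX_FIELDS:
        if f not in records_a.columns or f not in records_b.columns:
            continue
        fa = records_a[f].value_counts(normalize=True, dropna=True)
        fb = records_b[f].value_counts(normalize=True, dropna=True)
        agree = float((fa * fb.reindex(fa.index).fillna(0.0)).sum())
        u[f] = min(max(agree, 1e-7), 0.95 - 1e-7)
    return u


def default_model(records_a: pd.DataFrame, records_b: pd.DataFrame,
                  **overrides) -> LinkageModel:
    """m = 0.95 per field, u estimated from empirical field frequencies."""
    model = LinkageModel(u=estimate_u(records_a, records_b), **overrides)
    model.validate()
    return model


def _candidate_pairs(out_rec: pd.DataFrame, inp_rec: pd.DataFrame,
                     blocking: list) -> pd.DataFrame:
    pieces = []
    for block in blocking:
        keys = list(block)
        a = out_rec[["pseudo_id"] + keys].dropna(subset=keys)
        b = inp_rec[["pseudo_id"] + keys].dropna(subset=keys)
        a = a[~(a[keys].astype(str) == "").any(axis=1)]
        b = b[~(b[keys].astype(str) == "").any(axis=1)]
        merged = a.merge(b, on=keys, suffixes=("_out", "_inp"))
        pieces.append(merged[["pseudo_id_out", "pseudo_id_inp"]])
    if not pieces:
        return pd.DataFrame(columns=["pseudo_id_out", "pseudo_id_inp"])
    return pd.concat(pieces).drop_duplicates().reset_index(drop=True)


def _score_candidates(pairs: pd.DataFrame, out_rec: pd.DataFrame,
                      inp_rec: pd.DataFrame, model: LinkageModel) -> np.ndarray:
    a = out_rec.set_index("pseudo_id").loc[pairs["pseudo_id_out"]]
    b = inp_rec.set_index("pseudo_id").loc[pairs["pseudo_id_inp"]]
    score = np.zeros(len(pairs))
    for f, m in model.m.items():
        u = model.u.get(f)
        if u is None or f not in a.columns:
            continue
        va = a[f].to_numpy()
        vb = b[f].to_numpy()
        miss = (pd.isna(va) | pd.isna(vb)
                | (va.astype(str) == "") | (vb.astype(str) == ""))
        agree = (va == vb) & ~miss
        score += np.where(miss, 0.0,
                          np.where(agree, np.log2(m / u),
                                   np.log2((1.0 - m) / (1.0 - u))))
    return score


def link(outpatient: pd.DataFrame, inpatient: pd.DataFrame,
         model: LinkageModel | None = None) -> tuple[pd.DataFrame, dict]:
    """Link the two claim files into longitudinal patients.

    Returns ``(patients, audit)``. ``patients`` has one row per linked
    patient: patient_id, out_pseudo_id, inp_pseudo_id (either may be null
    for single-file patients), consensus demographics and the linkage
    score of the accepted pair.  Unmatched inpatient-only records are
    retained as patients (downstream eligibility, which requires drug
    claims, removes them).  Deterministic given input order.
    """
    if outpatient.empty or inpatient.empty:
        raise EmptyInputError("both claim streams must be non-empty")
    out_rec = aggregate_records(outpatient)
    inp_rec = aggregate_records(inpatient)
    if model is None:
        model = default_model(out_rec, inp_rec)
    model.validate()

    pairs = _candidate_pairs(out_rec, inp_rec, model.blocking)
    if len(pairs):
        pairs = pairs.copy()
        pairs["score"] = _score_candidates(pairs, out_rec, inp_rec, model)
        accepted_pool = pairs[pairs["score"] > model.threshold]
    else:
        pairs = pairs.assign(score=[])
        accepted_pool = pairs

    # greedy assignment by descending score, ties broken by stable record order
    order = accepted_pool.sort_values(
        ["score", "pseudo_id_out", "pseudo_id_inp"],
        ascending=[False, True, True], kind="mergesort")
    used_out: set = set()
    used_inp: set = set()
    accepted = []
    for row in order.itertuples(index=False):
        if row.pseudo_id_inp in used_inp:
            continue
        if model.one_to_one and row.pseudo_id_out in used_out:
            continue
        accepted.append((row.pseudo_id_out, row.pseudo_id_inp, row.score))
        used_out.add(row.pseudo_id_out)
        used_inp.add(row.pseudo_id_inp)

    matched = pd.DataFrame(accepted, columns=["out_pseudo_id", "inp_pseudo_id", "score"])
    out_only = out_rec.loc[~out_rec["pseudo_id"].isin(matched["out_pseudo_id"]), "pseudo_id"]
    inp_only = inp_rec.loc[~inp_rec["pseudo_id"].isin(matched["inp_pseudo_id"]), "pseudo_id"]
    patients = pd.concat([
        matched,
        pd.DataFrame({"out_pseudo_id": out_only, "inp_pseudo_id": None, "score": np.nan}),
        pd.DataFrame({"out_pseudo_id": None, "inp_pseudo_id": inp_only, "score": np.nan}),
    ], ignore_index=True)
    patients.insert(0, "patient_id", np.arange(len(patients)))

    # consensus demographics: majority over member rows of both files
    demo = _consensus_demographics(patients, outpatient, inpatient)
    patients = patients.merge(demo, on="patient_id", how="left")

    hist, edges = (np.array([]), np.array([]))
    if len(pairs):
        hist, edges = np.histogram(pairs["score"], bins=20)
    audit = {
        "n_outpatient_records": int(len(out_rec)),
        "n_inpatient_records": int(len(inp_rec)),
        "n_candidate_pairs": int(len(pairs)),
        "n_accepted_pairs": int(len(matched)),
        "threshold": model.threshold,
        "one_to_one": model.one_to_one,
        "u_probabilities": {k: float(v) for k, v in model.u.items()},
        "score_histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
    }
    return patients, audit


def _consensus_demographics(patients: pd.DataFrame, outpatient: pd.DataFrame,
                            inpatient: pd.DataFrame) -> pd.DataFrame:
    out_map = (patients.dropna(subset=["out_pseudo_id"])
               .set_index("out_pseudo_id")["patient_id"])
    inp_map = (patients.dropna(subset=["inp_pseudo_id"])
               .set_index("inp_pseudo_id")["patient_id"])
    fields = ["dob", "zip", "sex", "region"]
    rows = []
    for claims, mapping in ((outpatient, out_map), (inpatient, inp_map)):
        sub = claims[["pseudo_id"] + fields].copy()
        sub["patient_id"] = mapping.reindex(sub["pseudo_id"]).to_numpy()
        rows.append(sub.dropna(subset=["patient_id"]))
    pooled = pd.concat(rows, ignore_index=True)
    pooled["patient_id"] = pooled["patient_id"].astype(int)
    demo = pooled.groupby("patient_id")[fields].agg(_mode).reset_index()
    return demo


def claims_with_patient_ids(patients: pd.DataFrame, outpatient: pd.DataFrame,
                            inpatient: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag each raw claim row with its linked patient_id."""
    out_map = patients.dropna(subset=["out_pseudo_id"]).set_index("out_pseudo_id")["patient_id"]
    inp_map = patients.dropna(subset=["inp_pseudo_id"]).set_index("inp_pseudo_id")["patient_id"]
    out = outpatient.copy()
    out["patient_id"] = out_map.reindex(out["pseudo_id"]).to_numpy()
    inp = inpatient.copy()
    inp["patient_id"] = inp_map.reindex(inp["pseudo_id"]).to_numpy()
    return out, inp


def clean_inconsistent(records, max_missing_frac: float = 0.5,
                       dob_tolerance_days: int = 366) -> tuple[pd.DataFrame, dict]:
    """Drop or split records with inconsistent identifying data.

    On a raw claim frame: drops rows with more than ``max_missing_frac``
    of the key fields (dob, zip, icd10) missing.  When the frame carries a
    ``patient_id`` column, additionally splits any patient whose member
    rows disagree on dob by more than ``dob_tolerance_days`` (the
    conflicting file-halves get fresh patient ids and a flag).  Returns
    the cleaned frame and a log of counts.
    """
    df = records.copy()
    key_cols = [c for c in KEY_FIELDS if c in df.columns]
    missing = pd.DataFrame({
        c: df[c].isna() | (df[c].astype(str) == "") for c in key_cols})
    frac = missing.sum(axis=1) / max(len(key_cols), 1)
    keep = frac <= max_missing_frac
    dropped = int((~keep).sum())
    df = df[keep].copy()

    n_split = 0
    if "patient_id" in df.columns and "dob" in df.columns:
        df["dob_conflict"] = False
        max_id = pd.to_numeric(df["patient_id"], errors="coerce").max()
        next_id = int(max_id) + 1 if pd.notna(max_id) else 1
        for pid, grp in df.dropna(subset=["dob"]).groupby("patient_id"):
            spread = (grp["dob"].max() - grp["dob"].min()).days
            if spread > dob_tolerance_days:
                # irreconcilable dob: split the minority-dob rows off
                mode_dob = _mode(grp["dob"])
                off = grp.index[grp["dob"] != mode_dob]
                df.loc[grp.index, "dob_conflict"] = True
                df.loc[off, "patient_id"] = next_id
                next_id += 1
                n_split += 1
    info = {"rows_dropped_missing": dropped, "patients_split_dob": n_split}
    if dropped or n_split:
        log.info("clean_inconsistent: dropped %d sparse rows, split %d patients",
                 dropped, n_split)
    return df, info


def evaluate_linkage(patients: pd.DataFrame, true_pairs: pd.DataFrame,
                     restrict_to_present: pd.Series | None = None) -> dict:
    """Pairwise precision/recall/F1 of accepted pairs against ground truth.

    ``restrict_to_present`` optionally limits truth pairs to inpatient
    pseudo-IDs that actually occur in the inpatient file (patients with no
    stay cannot be linked and should not count as misses).
    """
    got = patients.dropna(subset=["out_pseudo_id", "inp_pseudo_id"])
    got_set = set(zip(got["out_pseudo_id"], got["inp_pseudo_id"]))
    truth = true_pairs
    if restrict_to_present is not None:
        truth = truth[truth["inp_pseudo_id"].isin(set(restrict_to_present))]
    true_set = set(zip(truth["out_pseudo_id"], truth["inp_pseudo_id"]))
    tp = len(got_set & true_set)
    precision = tp / len(got_set) if got_set else 1.0
    recall = tp / len(true_set) if true_set else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"tp": tp, "n_accepted": len(got_set), "n_true": len(true_set),
            "precision": precision, "recall": recall, "f1": f1}
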