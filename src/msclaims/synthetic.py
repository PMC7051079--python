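"""Synthetic DATASUS-like claims generator with known ground truth.

Emulates the structure of the Brazilian public-healthcare (SUS) claims
extract used for MS pharmacoepidemiology: two *unlinked* delimited files —
an outpatient drug-dispensing file and an inpatient stay file — that share
only noisy quasi-identifiers (date of birth, ZIP, sex, region, ICD-10).
Every patient starts on a first-line "platform" injectable; a configurable
fraction switches to second-line therapy, where the choice between
natalizumab and fingolimod follows a logistic model in observed
confounders, so that the naive between-drug comparison is biased.
Hospitalization events are Poisson with a per-patient rate equal to
baseline x line/drug effect x a mean-one confounder multiplier; same-day
infusion/monitoring stays are emitted deliberately so the ">1 day"
hospitalization rule has a real hazard to defend against.

The generator returns a :class:`GroundTruth` (true identities, true line
sequences, true treatment assignment, true events, true cross-file record
correspondence) so every downstream stage is testable without a download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .common import (
    ALL_DRUGS,
    DAYS_PER_YEAR,
    DIAGNOSTIC_CODE,
    DIMETHYL_FUMARATE,
    FINGOLIMOD,
    HOSPITAL_PROCEDURES,
    MS_ICD10,
    NATALIZUMAB,
    PLATFORM_DRUGS,
    PROC_FINGO_MONITOR,
    PROC_NAT_INFUSION,
    REGIONS,
    ConfigError,
    substream,
)

OUTPATIENT_COLUMNS = [
    "pseudo_id", "dispense_date", "drug_code", "icd10",
    "dob", "zip", "sex", "region",
]
INPATIENT_COLUMNS = [
    "pseudo_id", "admission_date", "discharge_date", "procedure_code",
    "procedure_quantity", "icd10", "dob", "zip", "sex", "region",
]


@dataclass
class ConfounderEffects:
    """Coefficients linking covariates to treatment choice and event rate.

    ``assignment`` feeds the logistic model for natalizumab (vs fingolimod)
    in second line; ``rate`` feeds the log-linear multiplier on the
    hospitalization rate.  Covariates are centred before use: ``age`` is
    (age - 34.7)/10.5, ``time_in_line1`` is (years - 1.6), region and
    first-line-glatiramer terms are mean-centred indicators.  The
    time-in-line-1 rate coefficient defaults to 0 so person-time weighting
    leaves the marginal first-line rate at its configured value.
    """

    assignment: dict = field(default_factory=lambda: {
        "intercept": 0.15, "age": 0.5, "region_south": -1.2,
        "region_northeast": 0.4, "line1_glatiramer": 0.3,
        "time_in_line1": -0.4,
    })
    rate: dict = field(default_factory=lambda: {
        "age": 0.35, "region_south": -0.6, "region_northeast": 0.3,
        "line1_glatiramer": 0.25, "time_in_line1": 0.0,
    })

    @classmethod
    def none(cls) -> "ConfounderEffects":
        """No confounding: assignment is a fair coin, rates homogeneous."""
        zero = {k: 0.0 for k in
                ("age", "region_south", "region_northeast",
                 "line1_glatiramer", "time_in_line1")}
        return cls(assignment={"intercept": 0.0, **zero}, rate=dict(zero))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic claims extract."""

    n_patients: int = 2000
    seed: int = 0
    study_start: date = date(2013, 1, 1)
    study_end: date = date(2017, 12, 31)
    platform_drugs: tuple = PLATFORM_DRUGS
    secondline_drugs: tuple = (NATALIZUMAB, FINGOLIMOD, DIMETHYL_FUMARATE) + PLATFORM_DRUGS
    true_rate_line1: float = 0.12          # events / person-year, first line
    true_rate_ratio_natalizumab: float = 0.30
    true_rate_ratio_fingolimod: float = 0.65
    true_rate_ratio_other: float = 0.85    # other post-platform drugs
    confounder_effects: ConfounderEffects = field(default_factory=ConfounderEffects)
    key_corruption_rate: float = 0.01      # per quasi-identifier field, per row
    dispense_interval_days: int = 30       # refill cadence == claim coverage
    gap_dropout_prob: float = 0.10         # interior refill skipped
    # population mixture (mutually exclusive special strata)
    frac_diagnostic_only: float = 0.02     # G35 work-up claims, never treated
    frac_underage: float = 0.04            # <18 at first claim
    frac_prewindow_start: float = 0.05     # started therapy before the window
    frac_nonplatform_first: float = 0.03   # first line not a platform drug
    frac_second_line: float = 0.78         # switch to a second line
    frac_natfingo: float = 0.55            # second line in {NAT, FINGO}
    frac_next_line: float = 0.25           # line k>=3 given line k-1
    region_probs: dict = field(default_factory=lambda: {
        "Southeast": 0.60, "South": 0.14, "Northeast": 0.13,
        "Centre-West": 0.10, "North": 0.03,
    })
    female_prob: float = 0.732

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be a positive integer")
        if self.study_end <= self.study_start:
            raise ConfigError("study_window is empty (study_end <= study_start)")
        for name in ("true_rate_line1", "true_rate_ratio_natalizumab",
                     "true_rate_ratio_fingolimod", "true_rate_ratio_other"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("key_corruption_rate", "gap_dropout_prob",
                     "frac_diagnostic_only", "frac_underage",
                     "frac_prewindow_start", "frac_nonplatform_first",
                     "frac_second_line", "frac_natfingo", "frac_next_line",
                     "female_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.dispense_interval_days <= 0:
            raise ConfigError("dispense_interval_days must be positive")
        if abs(sum(self.region_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("region_probs must sum to 1")

    def drug_rate_ratio(self, drug: str, line_number: int) -> float:
        if line_number == 1 and drug in self.platform_drugs:
            return 1.0
        if drug == NATALIZUMAB:
            return self.true_rate_ratio_natalizumab
        if drug == FINGOLIMOD:
            return self.true_rate_ratio_fingolimod
        return self.true_rate_ratio_other


@dataclass
class GroundTruth:
    """True identities, lines, assignment, events and pair correspondence.

    ``patients``: patient_id, out_pseudo_id, inp_pseudo_id, dob, sex, zip,
    region, first_ms_claim, first_treatment, age_at_first_claim,
    confounder_multiplier, stratum.
    ``lines``: patient_id, line_number, drug, start, end, n_refills,
    person_years, true_rate.
    ``hospitalizations``: hosp_id, patient_id, line_number, admission,
    discharge, los_days.
    ``procedures``: hosp_id, procedure_code, quantity.
    """

    config: SimulationConfig
    patients: pd.DataFrame
    lines: pd.DataFrame
    hospitalizations: pd.DataFrame
    procedures: pd.DataFrame

    def true_pairs(self) -> pd.DataFrame:
        """True (out_pseudo_id, inp_pseudo_id) correspondence."""
        return self.patients[["out_pseudo_id", "inp_pseudo_id"]].copy()

    def to_json(self, path) -> None:
        def frame(df):
            out = df.copy()
            for c in out.columns:
                if pd.api.types.is_datetime64_any_dtype(out[c]):
                    out[c] = out[c].dt.strftime("%Y-%m-%d")
            return out.to_dict(orient="list")

        payload = {
            "config": _config_to_dict(self.config),
            "patients": frame(self.patients),
            "lines": frame(self.lines),
            "hospitalizations": frame(self.hospitalizations),
            "procedures": frame(self.procedures),
        }
        Path(path).write_text(json.dumps(payload, indent=None, sort_keys=True))


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["study_start"] = config.study_start.isoformat()
    d["study_end"] = config.study_end.isoformat()
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("study_start", "study_end"):
        if key in d and isinstance(d[key], str):
            d[key] = date.fromisoformat(d[key])
    if "confounder_effects" in d and isinstance(d["confounder_effects"], dict):
        d["confounder_effects"] = ConfounderEffects(**d["confounder_effects"])
    for key in ("platform_drugs", "secondline_drugs"):
        if key in d:
            d[key] = tuple(d[key])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

_AGE_MEAN, _AGE_SD = 34.7, 10.5
_TLINE1_CENTER = 1.6  # years


def _centered(values: np.ndarray) -> np.ndarray:
    return values - values.mean()


def generate_population(config: SimulationConfig) -> GroundTruth:
    """Draw the ground-truth population: identities, lines, events."""
    config.validate()
    rng = np.random.default_rng(substream(config.seed, "population"))
    n = config.n_patients
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    span = (end - start).days
    step = config.dispense_interval_days

    # mutually exclusive special strata
    u = rng.random(n)
    edges = np.cumsum([config.frac_diagnostic_only, config.frac_underage,
                       config.frac_prewindow_start, config.frac_nonplatform_first])
    stratum = np.select(
        [u < edges[0], u < edges[1], u < edges[2], u < edges[3]],
        ["diagnostic_only", "underage", "prewindow", "nonplatform_first"],
        default="typical",
    )

    # demographics
    sex = np.where(rng.random(n) < config.female_prob, "F", "M")
    region_names = list(config.region_probs)
    region = rng.choice(region_names, size=n, p=list(config.region_probs.values()))
    zip_codes = np.array(["".join(d) for d in
                          rng.integers(0, 10, size=(n, 8)).astype(str)])
    age_z = np.clip(rng.standard_normal(n), -1.55, 3.8)
    age = _AGE_MEAN + _AGE_SD * age_z
    age[stratum == "underage"] = rng.uniform(14.0, 17.9, (stratum == "underage").sum())
    age_z = (age - _AGE_MEAN) / _AGE_SD

    # treatment start and first MS claim
    offset = np.where(rng.random(n) < 0.88,
                      rng.uniform(0, max(span - 540, 1), n),
                      rng.uniform(max(span - 540, 1), span - 30, n))
    pre = stratum == "prewindow"
    offset[pre] = -rng.uniform(30, 300, pre.sum())
    delay = np.where(rng.random(n) < 0.5,
                     rng.uniform(0, 60, n),
                     rng.exponential(300.0, n))
    delay = np.clip(delay, 0, 1095)
    # keep every claim within study window +/- 1 year
    delay[pre] = np.minimum(delay[pre], 360.0 + offset[pre])
    first_treatment = start + pd.to_timedelta(np.round(offset), unit="D")
    first_claim = first_treatment - pd.to_timedelta(np.round(delay), unit="D")
    dob = first_claim - pd.to_timedelta(np.round(age * DAYS_PER_YEAR), unit="D")

    # first-line drug
    platform = np.asarray(config.platform_drugs)
    line1_drug = rng.choice(platform, size=n, p=[0.27, 0.28, 0.14, 0.31]).astype(object)
    nonplat = stratum == "nonplatform_first"
    line1_drug[nonplat] = rng.choice([FINGOLIMOD, DIMETHYL_FUMARATE], nonplat.sum())

    # first-line duration in refills
    r1 = np.clip(np.round(np.exp(rng.normal(np.log(19.0), 0.55, n))), 2, 66).astype(int)
    tline1_years = r1 * step / DAYS_PER_YEAR

    # confounder multiplier on the hospitalization rate (mean one)
    is_south = (region == "South").astype(float)
    is_ne = (region == "Northeast").astype(float)
    is_glat = (line1_drug == "GLATIRAMER").astype(float)
    tline1_z = tline1_years - _TLINE1_CENTER
    g = config.confounder_effects.rate
    s = (g["age"] * _centered(age_z) + g["region_south"] * _centered(is_south)
         + g["region_northeast"] * _centered(is_ne)
         + g["line1_glatiramer"] * _centered(is_glat)
         + g["time_in_line1"] * _centered(tline1_z))
    multiplier = np.exp(s)
    multiplier /= multiplier.mean()

    # second line: switch indicator, drug choice (logistic for NAT vs FINGO)
    has_line2 = rng.random(n) < config.frac_second_line
    has_line2[stratum == "diagnostic_only"] = False
    natfingo = rng.random(n) < config.frac_natfingo
    b = config.confounder_effects.assignment
    logit = (b["intercept"] + b["age"] * age_z + b["region_south"] * is_south
             + b["region_northeast"] * is_ne + b["line1_glatiramer"] * is_glat
             + b["time_in_line1"] * tline1_z)
    p_nat = 1.0 / (1.0 + np.exp(-logit))
    choose_nat = rng.random(n) < p_nat

    line_rows = []
    treated = stratum != "diagnostic_only"
    other_pool = list(config.platform_drugs) + [DIMETHYL_FUMARATE]
    for i in np.nonzero(treated)[0]:
        drugs = [line1_drug[i]]
        refills = [r1[i]]
        if has_line2[i]:
            if natfingo[i] and line1_drug[i] in config.platform_drugs:
                d2 = NATALIZUMAB if choose_nat[i] else FINGOLIMOD
            else:
                pool = [d for d in other_pool if d != drugs[-1]]
                d2 = pool[rng.integers(len(pool))]
            drugs.append(d2)
            refills.append(int(np.clip(np.round(np.exp(rng.normal(np.log(15.0), 0.6))), 1, 48)))
            k = 3
            while k <= 4 and rng.random() < config.frac_next_line:
                pool = [d for d in ALL_DRUGS if d != drugs[-1]]
                drugs.append(pool[rng.integers(len(pool))])
                refills.append(int(np.clip(np.round(np.exp(rng.normal(np.log(10.0), 0.6))), 1, 36)))
                k += 1
        cursor = first_treatment[i]
        for ln, (drug, r) in enumerate(zip(drugs, refills), start=1):
            if cursor >= end:
                break
            room = (end - cursor).days // step
            r_eff = min(r, room)
            if r_eff < 1:
                break
            line_end = cursor + pd.Timedelta(days=r_eff * step)
            line_rows.append((i, ln, drug, cursor, line_end, r_eff))
            gap = step if (ln >= 1 and rng.random() < 0.15) else 0
            cursor = line_end + pd.Timedelta(days=gap)

    lines = pd.DataFrame(line_rows, columns=[
        "patient_id", "line_number", "drug", "start", "end", "n_refills"])
    lines["person_years"] = (lines["end"] - lines["start"]).dt.days / DAYS_PER_YEAR
    ratios = np.array([config.drug_rate_ratio(d, ln) for d, ln in
                       zip(lines["drug"], lines["line_number"])])
    lines["true_rate"] = (config.true_rate_line1 * ratios
                          * multiplier[lines["patient_id"].to_numpy()])

    # hospitalization events: Poisson per line
    counts = rng.poisson(lines["true_rate"].to_numpy() * lines["person_years"].to_numpy())
    hosp_rows, proc_rows = [], []
    hosp_id = 0
    proc_probs = np.array([0.76, 0.10, 0.05, 0.04, 0.02, 0.03])
    for (row, k) in zip(lines.itertuples(index=False), counts):
        dur = (row.end - row.start).days
        for _ in range(int(k)):
            los = 2 + int(rng.poisson(2.0))
            off = int(rng.integers(0, max(dur - los, 0) + 1))
            adm = row.start + pd.Timedelta(days=off)
            hosp_rows.append((hosp_id, row.patient_id, row.line_number,
                              adm, adm + pd.Timedelta(days=los), los))
            code = HOSPITAL_PROCEDURES[rng.choice(len(HOSPITAL_PROCEDURES), p=proc_probs)]
            qty = 1 + int(rng.poisson(7.0 if code == HOSPITAL_PROCEDURES[0] else 1.0))
            proc_rows.append((hosp_id, code, qty))
            hosp_id += 1
    hosp = pd.DataFrame(hosp_rows, columns=[
        "hosp_id", "patient_id", "line_number", "admission", "discharge", "los_days"])
    procedures = pd.DataFrame(proc_rows, columns=["hosp_id", "procedure_code", "quantity"])

    # opaque, disjoint pseudo-identifier spaces
    out_ids = np.array([f"O{v:07d}" for v in rng.permutation(n) + 1])
    inp_ids = np.array([f"H{v:07d}" for v in rng.permutation(n) + 1])

    patients = pd.DataFrame({
        "patient_id": np.arange(n),
        "out_pseudo_id": out_ids,
        "inp_pseudo_id": inp_ids,
        "dob": dob,
        "sex": sex,
        "zip": zip_codes,
        "region": region,
        "first_ms_claim": first_claim,
        "first_treatment": first_treatment,
        "age_at_first_claim": age,
        "confounder_multiplier": multiplier,
        "stratum": stratum,
    })
    return GroundTruth(config=config, patients=patients, lines=lines,
                       hospitalizations=hosp, procedures=procedures)


# ---------------------------------------------------------------------------
# claim-file emission
# ---------------------------------------------------------------------------

def _corrupt_fields(df: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Independently corrupt quasi-identifier fields at the given rate.

    dob: +/- 1 day; zip: one-digit substitution (or blanked, 20% of hits);
    sex: flipped.
    """
    if rate <= 0 or df.empty:
        return df
    m = len(df)
    hit = rng.random(m) < rate
    if hit.any():
        shift = rng.choice([-1, 1], size=m)
        dob = df["dob"].to_numpy().copy()
        dob[hit] = dob[hit] + shift[hit].astype("timedelta64[D]")
        df["dob"] = dob
    hit = rng.random(m) < rate
    if hit.any():
        zips = df["zip"].to_numpy().astype(object)
        for j in np.nonzero(hit)[0]:
            if rng.random() < 0.2:
                zips[j] = ""
            else:
                z = list(zips[j])
                pos = int(rng.integers(len(z)))
                z[pos] = str((int(z[pos]) + 1 + int(rng.integers(9))) % 10)
                zips[j] = "".join(z)
        df["zip"] = zips
    hit = rng.random(m) < rate
    if hit.any():
        df.loc[hit, "sex"] = np.where(df.loc[hit, "sex"] == "F", "M", "F")
    return df


def emit_claim_files(truth: GroundTruth,
                     config: SimulationConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the two unlinked claim files from the ground truth.

    Outpatient: one work-up claim at the first MS claim date plus refill
    dispensings at the configured cadence (interior refills dropped with
    ``gap_dropout_prob``; the first and last refill of a line are always
    kept).  Inpatient: one row per true hospitalization, plus same-day
    infusion stays for natalizumab lines and a first-dose monitoring stay
    (0-1 days) for fingolimod lines.
    """
    config = config or truth.config
    rng = np.random.default_rng(substream(config.seed, "emission"))
    step = config.dispense_interval_days
    pat = truth.patients.set_index("patient_id")

    out_rows = []
    # diagnostic work-up claims
    for pid, fc in zip(truth.patients["patient_id"], truth.patients["first_ms_claim"]):
        out_rows.append((pid, fc, DIAGNOSTIC_CODE))
        if pat.loc[pid, "stratum"] == "diagnostic_only":
            out_rows.append((pid, fc + pd.Timedelta(days=60), DIAGNOSTIC_CODE))
    # dispensing refills
    for row in truth.lines.itertuples(index=False):
        r = int(row.n_refills)
        keep = np.ones(r, dtype=bool)
        if r > 2:
            keep[1:-1] = rng.random(r - 2) >= config.gap_dropout_prob
        for j in np.nonzero(keep)[0]:
            out_rows.append((row.patient_id,
                             row.start + pd.Timedelta(days=int(j) * step),
                             row.drug))
    outpatient = pd.DataFrame(out_rows, columns=["patient_id", "dispense_date", "drug_code"])

    inp_rows = []
    proc = truth.procedures.set_index("hosp_id")
    for h in truth.hospitalizations.itertuples(index=False):
        p = proc.loc[h.hosp_id]
        inp_rows.append((h.patient_id, h.admission, h.discharge,
                         p["procedure_code"], int(p["quantity"])))
    # same-day treatment-requirement stays (the hazard the >1-day rule avoids)
    for row in truth.lines.itertuples(index=False):
        if row.drug == NATALIZUMAB:
            t = row.start
            while t < row.end:
                if rng.random() < 0.9:
                    inp_rows.append((row.patient_id, t, t, PROC_NAT_INFUSION, 1))
                t = t + pd.Timedelta(days=28)
        elif row.drug == FINGOLIMOD:
            los = int(rng.integers(0, 2))
            inp_rows.append((row.patient_id, row.start,
                             row.start + pd.Timedelta(days=los), PROC_FINGO_MONITOR, 1))
    inpatient = pd.DataFrame(inp_rows, columns=[
        "patient_id", "admission_date", "discharge_date",
        "procedure_code", "procedure_quantity"])

    # attach quasi-identifiers and pseudo-IDs
    demo = pat[["dob", "zip", "sex", "region"]]
    outpatient = outpatient.join(demo, on="patient_id")
    outpatient["pseudo_id"] = pat["out_pseudo_id"].reindex(outpatient["patient_id"]).to_numpy()
    outpatient["icd10"] = MS_ICD10
    inpatient = inpatient.join(demo, on="patient_id")
    inpatient["pseudo_id"] = pat["inp_pseudo_id"].reindex(inpatient["patient_id"]).to_numpy()
    inpatient["icd10"] = MS_ICD10

    outpatient = _corrupt_fields(outpatient, config.key_corruption_rate, rng)
    inpatient = _corrupt_fields(inpatient, config.key_corruption_rate, rng)

    outpatient = outpatient[OUTPATIENT_COLUMNS + ["patient_id"]]
    inpatient = inpatient[INPATIENT_COLUMNS + ["patient_id"]]
    outpatient = outpatient.iloc[rng.permutation(len(outpatient))].reset_index(drop=True)
    inpatient = inpatient.iloc[rng.permutation(len(inpatient))].reset_index(drop=True)
    return outpatient.drop(columns="patient_id"), inpatient.drop(columns="patient_id")


def simulate(config: SimulationConfig) -> tuple[GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Generate the population and emit both claim files."""
    truth = generate_population(config)
    outpatient, inpatient = emit_claim_files(truth, config)
    return truth, outpatient, inpatient


def write_claims(outpatient: pd.DataFrame, inpatient: pd.DataFrame, outdir) -> dict:
    """Write the two CSV extracts with ISO-8601 dates; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"outpatient": outdir / "outpatient.csv",
             "inpatient": outdir / "inpatient.csv"}
    for name, df in (("outpatient", outpatient), ("inpatient", inpatient)):
        out = df.copy()
        for c in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[c]):
                out[c] = out[c].dt.strftime("%Y-%m-%d")
        out.to_csv(paths[name], index=False)
    return paths


def read_claims(outpatient_path, inpatient_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the two CSV extracts, parsing dates and keeping ZIP fixed-width."""
    out = pd.read_csv(outpatient_path, dtype={"zip": str, "pseudo_id": str},
                      parse_dates=["dispense_date", "dob"], keep_default_na=False,
                      na_values=[])
    inp = pd.read_csv(inpatient_path, dtype={"zip": str, "pseudo_id": str},
                      parse_dates=["admission_date", "discharge_date", "dob"],
                      keep_default_na=False, na_values=[])
    return out, inp
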