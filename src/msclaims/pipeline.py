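"""Pipeline orchestration: simulate -> link -> lines -> cohorts -> adjust
-> outcomes, with per-stage artifacts and a deterministic manifest.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be re-run individually from the CLI.  A single
global seed is fanned out to named substreams per stage; the manifest
records the seed, a hash of the configuration and the SHA-256 of every
artifact, so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import adjustment, analysis, cohorts, linkage, outcomes, synthetic, therapy
from .common import FINGOLIMOD, NATALIZUMAB, file_sha256, get_logger, substream

log = get_logger(__name__)

STAGES = ("simulate", "link", "lines", "cohorts", "adjust", "outcomes")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Full pipeline configuration (YAML-loadable).

    ``simulation`` is a SimulationConfig field dict, or None when real
    extract paths are supplied via ``outpatient_csv``/``inpatient_csv``.
    """

    seed: int = 0
    simulation: dict | None = dataclasses.field(default_factory=dict)
    outpatient_csv: str | None = None
    inpatient_csv: str | None = None
    linkage: dict = dataclasses.field(default_factory=dict)       # threshold, one_to_one
    episodes: dict = dataclasses.field(default_factory=dict)      # grace_days, coverage_days
    cohort: dict = dataclasses.field(default_factory=dict)        # window_start, window_end
    adjustment: dict = dataclasses.field(default_factory=dict)    # caliper, ipw_mode, ...
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def simulation_config(self) -> synthetic.SimulationConfig:
        block = dict(self.simulation or {})
        block.setdefault("seed", self.seed)
        return synthetic.config_from_dict(block)

    def study_window(self) -> cohorts.StudyWindow:
        w = cohorts.StudyWindow()
        if self.cohort.get("window_start"):
            w.start = date.fromisoformat(str(self.cohort["window_start"]))
        if self.cohort.get("window_end"):
            w.end = date.fromisoformat(str(self.cohort["window_end"]))
        return w


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def _read_lines(rundir: Path) -> pd.DataFrame:
    return pd.read_csv(rundir / "lines.csv", parse_dates=["start", "end"])


def _read_linked_claims(rundir: Path):
    out = pd.read_csv(rundir / "outpatient_linked.csv",
                      dtype={"zip": str, "pseudo_id": str},
                      parse_dates=["dispense_date", "dob"])
    inp = pd.read_csv(rundir / "inpatient_linked.csv",
                      dtype={"zip": str, "pseudo_id": str},
                      parse_dates=["admission_date", "discharge_date", "dob"])
    return out, inp


def stage_simulate(config: RunConfig, rundir: Path) -> None:
    sim = config.simulation_config()
    truth, out_df, inp_df = synthetic.simulate(sim)
    synthetic.write_claims(out_df, inp_df, rundir)
    truth.to_json(rundir / "ground_truth.json")


def stage_link(config: RunConfig, rundir: Path) -> None:
    out_path = (Path(config.outpatient_csv) if config.outpatient_csv
                else rundir / "outpatient.csv")
    inp_path = (Path(config.inpatient_csv) if config.inpatient_csv
                else rundir / "inpatient.csv")
    out_df, inp_df = synthetic.read_claims(out_path, inp_path)
    out_rec = linkage.aggregate_records(out_df)
    inp_rec = linkage.aggregate_records(inp_df)
    model = linkage.default_model(
        out_rec, inp_rec,
        threshold=float(config.linkage.get("threshold", 0.0)),
        one_to_one=bool(config.linkage.get("one_to_one", True)))
    patients, audit = linkage.link(out_df, inp_df, model)
    out_tag, inp_tag = linkage.claims_with_patient_ids(patients, out_df, inp_df)
    out_tag, clean_info = linkage.clean_inconsistent(out_tag)
    inp_tag, clean_info2 = linkage.clean_inconsistent(inp_tag)
    audit["cleaning"] = {"outpatient": clean_info, "inpatient": clean_info2}
    _write_csv(patients, rundir / "linked_patients.csv")
    _write_csv(out_tag, rundir / "outpatient_linked.csv")
    _write_csv(inp_tag, rundir / "inpatient_linked.csv")
    _write_json(audit, rundir / "linkage_audit.json")


def stage_lines(config: RunConfig, rundir: Path) -> None:
    out_tag, _ = _read_linked_claims(rundir)
    eps = therapy.build_episodes(
        out_tag,
        grace_days=int(config.episodes.get("grace_days", therapy.DEFAULT_GRACE_DAYS)),
        coverage_days=int(config.episodes.get("coverage_days", therapy.DEFAULT_COVERAGE_DAYS)))
    lines = therapy.assign_lines(eps)
    _write_csv(eps, rundir / "episodes.csv")
    _write_csv(lines, rundir / "lines.csv")
    _write_csv(therapy.summarize_patterns(lines), rundir / "treatment_patterns.csv")
    for k in (1, 2, 3):
        _write_csv(therapy.switch_matrix(lines, k),
                   rundir / f"switch_matrix_line{k}.csv")


def stage_cohorts(config: RunConfig, rundir: Path) -> None:
    out_tag, inp_tag = _read_linked_claims(rundir)
    lines = _read_lines(rundir)
    patients = pd.read_csv(rundir / "linked_patients.csv",
                           dtype={"zip": str}, parse_dates=["dob"])
    elig = cohorts.build_eligibility(patients, out_tag, inp_tag, lines,
                                     window=config.study_window())
    assign1, attrition = cohorts.evaluate_cohort1(elig)
    assign = cohorts.evaluate_cohort2(assign1, elig)
    cov = cohorts.build_covariates(elig, patients, lines)
    members = assign[assign["in_cohort2"]]
    _write_csv(elig, rundir / "eligibility.csv")
    _write_json(attrition, rundir / "attrition.json")
    _write_csv(assign, rundir / "cohort_assignments.csv")
    _write_csv(cov, rundir / "covariates.csv")
    if len(members) >= 4:
        arm = members.merge(cov, on="patient_id")
        base = cohorts.baseline_table(
            arm.drop(columns=["in_cohort1", "in_cohort2", "cohort2_arm"]),
            arm["cohort2_arm"])
        _write_csv(base, rundir / "baseline_unmatched.csv")


def stage_adjust_and_outcomes(config: RunConfig, rundir: Path) -> None:
    """Classification, AHR tables and PS/IPW-adjusted comparisons."""
    out_tag, inp_tag = _read_linked_claims(rundir)
    lines = _read_lines(rundir)
    assign = pd.read_csv(rundir / "cohort_assignments.csv")
    cov = pd.read_csv(rundir / "covariates.csv")

    hosp, procs = outcomes.classify_hospitalizations(
        inp_tag.rename(columns={}), lines)
    _write_csv(hosp, rundir / "hospitalizations.csv")
    _write_csv(procs, rundir / "procedures.csv")

    cohort1_ids = set(assign.loc[assign["in_cohort1"], "patient_id"])
    hosp1 = hosp[hosp["patient_id"].isin(cohort1_ids)]
    _write_csv(outcomes.procedure_profile(hosp1, procs),
               rundir / "procedure_profile.csv")

    members = assign[assign["in_cohort2"]]
    n_arms = members["cohort2_arm"].nunique()
    if members.empty or n_arms < 2 or len(members) < 8:
        _write_json({"skipped": "cohort 2 empty or single-arm"},
                    rundir / "ahr_table_skipped.json")
        return
    frame = analysis.build_analysis_frame(cov, assign, hosp, lines)
    adj = config.adjustment
    result = analysis.cohort2_analysis(
        frame,
        seed=substream(config.seed, "matching"),
        caliper=adj.get("caliper", adjustment.DEFAULT_CALIPER),
        ipw_mode=adj.get("ipw_mode", "standard"),
        stabilized=bool(adj.get("stabilized", False)),
        truncate_percentile=adj.get("truncate_percentile", 99.0),
        penalized=bool(adj.get("penalized", False)))
    _write_csv(result["table"], rundir / "ahr_table.csv")
    _write_csv(result["ps"], rundir / "weights.csv")
    _write_csv(result["matched"].pairs, rundir / "matched_pairs.csv")
    _write_csv(result["balance_matched"], rundir / "balance_matched.csv")
    _write_csv(result["balance_ipw"], rundir / "balance_ipw.csv")
    _write_json({k: float(v) for k, v in result["ps_params"].items()},
                rundir / "ps_coefficients.json")

    arm_map = members.set_index("patient_id")["cohort2_arm"]
    matched_ids = set(result["matched"].patient_ids)
    util = outcomes.stratum_utilization(
        hosp[hosp["patient_id"].isin(matched_ids)], procs,
        arm_map[arm_map.index.isin(matched_ids)])
    _write_csv(util, rundir / "utilization_by_arm.csv")


def run(config: RunConfig, rundir) -> dict:
    """Execute the full pipeline; returns the manifest."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    logging.getLogger("msclaims").setLevel(config.log_level)

    stage_fns = [
        ("simulate", stage_simulate) if config.simulation is not None else None,
        ("link", stage_link),
        ("lines", stage_lines),
        ("cohorts", stage_cohorts),
        ("outcomes", stage_adjust_and_outcomes),
    ]
    for item in stage_fns:
        if item is None:
            continue
        name, fn = item
        log.info("running stage %s", name)
        try:
            fn(config, rundir)
        except Exception as exc:
            raise StageError(name, exc) from exc
    manifest = build_manifest(config, rundir)
    _write_json(manifest, rundir / "manifest.json")
    return manifest


def build_manifest(config: RunConfig, rundir: Path) -> dict:
    import hashlib

    artifacts = {}
    for path in sorted(Path(rundir).glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        entry = {"sha256": file_sha256(path), "bytes": path.stat().st_size}
        if path.suffix == ".csv":
            with open(path) as fh:
                entry["rows"] = max(sum(1 for _ in fh) - 1, 0)
        artifacts[path.name] = entry
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"seed": config.seed, "config_sha256": cfg_hash,
            "artifacts": artifacts}


def report(rundir) -> str:
    """Render a human-readable run summary from stage artifacts only."""
    rundir = Path(rundir)
    lines_ = []
    add = lines_.append
    add("MS claims pipeline run summary")
    add("=" * 34)
    attr_path = rundir / "attrition.json"
    if not attr_path.exists():
        raise FileNotFoundError(f"missing artifact: {attr_path}")
    attrition = json.loads(attr_path.read_text())
    add("Attrition funnel:")
    add(f"  screened patients: {attrition['screened']}")
    for key, val in attrition.items():
        if key.startswith("excluded_"):
            add(f"  excluded ({key[9:]}): {val}")
    add(f"  cohort 1: {attrition['cohort1']}")

    assign = pd.read_csv(rundir / "cohort_assignments.csv")
    members = assign[assign["in_cohort2"]]
    add(f"  cohort 2: {len(members)} "
        f"(natalizumab {int((members['cohort2_arm'] == NATALIZUMAB).sum())}, "
        f"fingolimod {int((members['cohort2_arm'] == FINGOLIMOD).sum())})")

    patt = rundir / "treatment_patterns.csv"
    if patt.exists():
        df = pd.read_csv(patt)
        add("")
        add("Treatment patterns (per line, top drugs):")
        for ln, grp in df.groupby("line_number"):
            top = grp.sort_values("n", ascending=False).head(3)
            parts = [f"{r.drug_code} {r.n} ({r.pct:.1f}%)" for r in top.itertuples()]
            add(f"  line {ln}: " + "; ".join(parts))

    ahr = rundir / "ahr_table.csv"
    if ahr.exists():
        df = pd.read_csv(ahr)
        add("")
        add("Annualized hospitalization rates (events/person-year):")
        for r in df.itertuples():
            if r.measure == "difference_line1_minus_line2":
                add(f"  [{r.analysis}] {r.arm}: difference {r.difference:.3f} "
                    f"({r.ci_low:.3f} to {r.ci_high:.3f}), "
                    f"reduction {r.percent_reduction:.1f}%, p={r.p_value:.4g}")
            elif r.measure == "second_line_fingolimod_minus_natalizumab":
                add(f"  [{r.analysis}] fingolimod vs natalizumab second-line "
                    f"difference {r.difference:.3f}, p={r.p_value:.4g}")
            else:
                add(f"  [{r.analysis}] {r.arm} {r.measure}: "
                    f"AHR {r.rate:.3f} ({r.ci_low:.2f}-{r.ci_high:.2f})")
    elif (rundir / "ahr_table_skipped.json").exists():
        add("")
        add("Cohort-2 rate comparison skipped (empty or single-arm cohort 2).")

    prof = rundir / "procedure_profile.csv"
    if prof.exists():
        df = pd.read_csv(prof).head(5)
        add("")
        add("Most frequent inpatient procedures (cohort 1):")
        for r in df.itertuples():
            add(f"  {r.procedure_code}: {r.total} ({r.pct:.2f}%), "
                f"median per hospitalized patient {r.per_patient_median:.0f}")
    text = "\n".join(lines_) + "\n"
    (rundir / "report.txt").write_text(text)
    return text
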