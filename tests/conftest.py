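import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import msclaims as mc
from msclaims import linkage, therapy

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_sim():
    """Zero-corruption synthetic extract: exact keys, full ground truth."""
    cfg = mc.SimulationConfig(n_patients=400, seed=5, key_corruption_rate=0.0)
    truth, out, inp = mc.simulate(cfg)
    return cfg, truth, out, inp


@pytest.fixture(scope="session")
def noisy_sim():
    """Default 1% key-corruption synthetic extract."""
    cfg = mc.SimulationConfig(n_patients=500, seed=1)
    truth, out, inp = mc.simulate(cfg)
    return cfg, truth, out, inp


@pytest.fixture(scope="session")
def linked_clean(clean_sim):
    """Stage outputs (linked patients, tagged claims, lines) on clean data."""
    cfg, truth, out, inp = clean_sim
    patients, audit = linkage.link(out, inp)
    out_tag, inp_tag = linkage.claims_with_patient_ids(patients, out, inp)
    lines = therapy.assign_lines(therapy.build_episodes(out_tag))
    return {"cfg": cfg, "truth": truth, "patients": patients, "audit": audit,
            "out_tag": out_tag, "inp_tag": inp_tag, "lines": lines}


def make_truth(cfg, patients_rows, lines_rows, hosp_rows, proc_rows=None):
    """Hand-build a GroundTruth from plain tuples (test helper)."""
    patients = pd.DataFrame(patients_rows, columns=[
        "patient_id", "out_pseudo_id", "inp_pseudo_id", "dob", "sex", "zip",
        "region", "first_ms_claim", "first_treatment", "age_at_first_claim",
        "confounder_multiplier", "stratum"])
    for c in ("dob", "first_ms_claim", "first_treatment"):
        patients[c] = pd.to_datetime(patients[c])
    lines = pd.DataFrame(lines_rows, columns=[
        "patient_id", "line_number", "drug", "start", "end", "n_refills"])
    for c in ("start", "end"):
        lines[c] = pd.to_datetime(lines[c])
    lines["person_years"] = (lines["end"] - lines["start"]).dt.days / 365.25
    lines["true_rate"] = 0.12
    hosp = pd.DataFrame(hosp_rows, columns=[
        "hosp_id", "patient_id", "line_number", "admission", "discharge",
        "los_days"])
    for c in ("admission", "discharge"):
        hosp[c] = pd.to_datetime(hosp[c])
    procedures = pd.DataFrame(
        proc_rows or [(h[0], "MS_RELAPSE_TREATMENT", 1) for h in hosp_rows],
        columns=["hosp_id", "procedure_code", "quantity"])
    return mc.GroundTruth(config=cfg, patients=patients, lines=lines,
                          hospitalizations=hosp, procedures=procedures)
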