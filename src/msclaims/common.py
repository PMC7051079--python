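"""Shared constants, errors and seeding helpers."""

from __future__ import annotations

import hashlib
import logging

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

# MS disease-modifying therapies dispensed through the public pharmacy
# programme.  Platform (first-line injectable) drugs vs. later-line options.
PLATFORM_DRUGS = (
    "IFN_BETA_1A_IM",
    "IFN_BETA_1A_SC",
    "IFN_BETA_1B_SC",
    "GLATIRAMER",
)
NATALIZUMAB = "NATALIZUMAB"
FINGOLIMOD = "FINGOLIMOD"
DIMETHYL_FUMARATE = "DIMETHYL_FUMARATE"
SECONDLINE_DRUGS = (NATALIZUMAB, FINGOLIMOD, DIMETHYL_FUMARATE) + PLATFORM_DRUGS
ALL_DRUGS = PLATFORM_DRUGS + (NATALIZUMAB, FINGOLIMOD, DIMETHYL_FUMARATE)

# Non-drug outpatient claim marking a diagnostic work-up visit (defines the
# first MS claim date without being a dispensing record).
DIAGNOSTIC_CODE = "G35_WORKUP"

MS_ICD10 = "G35"

REGIONS = ("North", "Northeast", "Centre-West", "Southeast", "South")

# Small SIGTAP-like dictionary of inpatient procedure codes.
PROC_RELAPSE = "MS_RELAPSE_TREATMENT"
PROC_CENTRAL_MOTOR = "CENTRAL_MOTOR_NEURON_TREATMENT"
PROC_PHYSIO = "MOTOR_PHYSIOTHERAPY"
PROC_PROLONGED = "PROLONGED_NEURO_TREATMENT"
PROC_EMERGENCY = "EMERGENCY_CLINICAL_CARE"
PROC_MRI = "CRANIUM_MRI"
PROC_NAT_INFUSION = "NATALIZUMAB_INFUSION"
PROC_FINGO_MONITOR = "FINGOLIMOD_FIRST_DOSE_MONITORING"
HOSPITAL_PROCEDURES = (
    PROC_RELAPSE,
    PROC_CENTRAL_MOTOR,
    PROC_PHYSIO,
    PROC_PROLONGED,
    PROC_EMERGENCY,
    PROC_MRI,
)


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


class EmptyInputError(ValueError):
    """Raised when a stage receives an empty claim stream."""


def substream(seed: int, name: str) -> int:
    """Derive a named, independent 31-bit child seed from a global seed.

    Stages draw from named substreams so that changing one stage's
    parameters never shifts another stage's random draws.
    """
    digest = hashlib.sha256(f"{int(seed)}/{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def get_logger(name: str) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logging.getLogger("msclaims").handlers:
        logging.getLogger("msclaims").addHandler(logging.NullHandler())
    return logger
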