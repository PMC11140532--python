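"""Simulated patient population: demographics, biomarkers, and treatment assignment.

Attributes mirror the trial population driving the model: sex-specific body
weight, body-surface area (DuBois) and serum creatinine, median age, histology
and the three biomarkers (PD-L1 tumor proportion score category, *EGFR*
mutation, *ALK* rearrangement) that route patients to their first
post-progression regimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatientProfile",
    "PopulationPriors",
    "US_PRIORS",
    "generate_patients",
    "assign_pod1_regimen",
    "apply_country_policy",
    "POD2_REGIMEN",
]

FEMALE = "female"
MALE = "male"
SQUAMOUS = "squamous"
NONSQUAMOUS = "nonsquamous"
TPS_GE1 = "tps_ge1"
TPS_LT1 = "tps_lt1"
TPS_UNKNOWN = "unknown"

POD2_REGIMEN = "docetaxel"


@dataclass(frozen=True)
class PatientProfile:
    sex: str
    weight: float  # kg
    bsa: float  # m^2
    serum_creatinine: float  # mg/dL
    age: float  # years
    histology: str
    pdl1: str
    egfr_mutant: bool
    alk_rearranged: bool

    def __post_init__(self):
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.histology not in (SQUAMOUS, NONSQUAMOUS):
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.pdl1 not in (TPS_GE1, TPS_LT1, TPS_UNKNOWN):
            raise ValueError(f"unknown PD-L1 category {self.pdl1!r}")
        if self.egfr_mutant and self.alk_rearranged:
            raise ValueError("EGFR mutation and ALK rearrangement are mutually exclusive")


@dataclass(frozen=True)
class PopulationPriors:
    """Prevalence and demographic inputs for patient generation (US base case)."""

    female_fraction: float = 0.299
    weight_female: float = 77.5
    weight_male: float = 90.6
    bsa_female: float = 1.82
    bsa_male: float = 2.06
    creatinine_female: float = 0.96
    creatinine_male: float = 1.16
    age: float = 64.0
    squamous_fraction: float = 0.457
    pdl1_ge1: float = 0.425
    pdl1_lt1: float = 0.208
    pdl1_unknown: float = 0.367
    egfr_fraction: float = 0.06
    alk_fraction: float = 0.0112

    def __post_init__(self):
        for name in (
            "female_fraction",
            "squamous_fraction",
            "pdl1_ge1",
            "pdl1_lt1",
            "pdl1_unknown",
            "egfr_fraction",
            "alk_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.pdl1_ge1 + self.pdl1_lt1 + self.pdl1_unknown - 1.0) > 1e-6:
            raise ValueError("PD-L1 category prevalences must sum to 1")
        if self.egfr_fraction + self.alk_fraction > 1.0:
            raise ValueError("EGFR + ALK prevalences exceed 1")


US_PRIORS = PopulationPriors()


def generate_patients(
    n: int, priors: PopulationPriors = US_PRIORS, seed: int = 0
) -> list[PatientProfile]:
    """Draw ``n`` independent patient profiles from the configured prevalences.

    Each patient gets a dedicated RNG stream derived from ``(seed, index)``, so
    patient ``i`` is identical regardless of cohort size.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    patients = []
    for i in range(n):
        rng = np.random.default_rng([int(seed) % (2**31), i])
        u_sex, u_hist, u_pdl1, u_driver = rng.random(4)
        female = u_sex < priors.female_fraction
        squamous = u_hist < priors.squamous_fraction
        if u_pdl1 < priors.pdl1_ge1:
            pdl1 = TPS_GE1
        elif u_pdl1 < priors.pdl1_ge1 + priors.pdl1_lt1:
            pdl1 = TPS_LT1
        else:
            pdl1 = TPS_UNKNOWN
        # single categorical draw keeps EGFR/ALK mutually exclusive with exact marginals
        egfr = u_driver < priors.egfr_fraction
        alk = (not egfr) and u_driver < priors.egfr_fraction + priors.alk_fraction
        patients.append(
            PatientProfile(
                sex=FEMALE if female else MALE,
                weight=priors.weight_female if female else priors.weight_male,
                bsa=priors.bsa_female if female else priors.bsa_male,
                serum_creatinine=priors.creatinine_female if female else priors.creatinine_male,
                age=priors.age,
                histology=SQUAMOUS if squamous else NONSQUAMOUS,
                pdl1=pdl1,
                egfr_mutant=bool(egfr),
                alk_rearranged=bool(alk),
            )
        )
    return patients


def assign_pod1_regimen(p: PatientProfile) -> str:
    """Regimen at first progression, by biomarker status and histology.

    Oncogene-driven disease gets targeted therapy; PD-L1 positive or unknown
    tumors get pembrolizumab plus platinum doublet; PD-L1 negative tumors get
    the platinum doublet alone.  Second progression is always docetaxel.
    """
    if p.egfr_mutant:
        return "osimertinib"
    if p.alk_rearranged:
        return "alectinib"
    if p.pdl1 in (TPS_GE1, TPS_UNKNOWN):
        return (
            "pembrolizumab_combo_nonsquamous"
            if p.histology == NONSQUAMOUS
            else "pembrolizumab_combo_squamous"
        )
    return "chemo_nonsquamous" if p.histology == NONSQUAMOUS else "chemo_squamous"


def apply_country_policy(p: PatientProfile, arm: str, country) -> str:
    """Apply reimbursement gating: where durvalumab requires PD-L1 TPS >= 1%,
    TPS-negative patients in the durvalumab strategy follow the placebo pathway."""
    if arm == "durvalumab" and getattr(country, "pdl1_gate", False) and p.pdl1 == TPS_LT1:
        return "placebo"
    return arm
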