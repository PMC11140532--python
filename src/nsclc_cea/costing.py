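"""Country-specific costing: drug acquisition, administration, adverse events,
supportive and end-of-life care, with discounting and currency conversion.

All accounting is in US dollars; native-currency inputs are converted once at
configuration load.  Dosing follows the label rules (mg/kg, mg/m^2, flat, oral
monthly) with carboplatin dosed by the Calvert formula using Cockcroft-Gault
creatinine clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .patients import FEMALE, PatientProfile

__all__ = [
    "Utilities",
    "CountryConfig",
    "DrugComponent",
    "Regimen",
    "AccessProgram",
    "REGIMENS",
    "AE_INCIDENCE",
    "ConfigurationError",
    "dose_amount",
    "discount_value",
    "convert_currency",
    "regimen_cost",
    "adverse_event_cost",
    "access_program_price_per_mg",
    "creatinine_clearance",
]

DAYS_PER_MONTH = 30.0
CRCL_CAP_ML_MIN = 125.0


class ConfigurationError(ValueError):
    """Raised for incomplete or inconsistent cost configuration."""


@dataclass
class Utilities:
    """Health-state utilities; post-progression states share one value."""

    pfs: float = 0.79
    pod: float = 0.76
    death: float = 0.0
    # arm-specific override of the progression-free utility (sensitivity analyses
    # vary the durvalumab PFS utility on its own); None means "same as pfs".
    pfs_durvalumab: float | None = None

    def __post_init__(self):
        for name in ("pfs", "pod", "death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"utility {name}={v} outside [0, 1]")
        if self.death != 0.0:
            raise ConfigurationError("death utility must be 0")
        if self.pfs_durvalumab is not None and not 0.0 <= self.pfs_durvalumab <= 1.0:
            raise ConfigurationError("pfs_durvalumab utility outside [0, 1]")

    def pfs_for_arm(self, effective_arm: str) -> float:
        if effective_arm == "durvalumab" and self.pfs_durvalumab is not None:
            return self.pfs_durvalumab
        return self.pfs


@dataclass(frozen=True)
class AccessProgram:
    """Vial-based industry access scheme for durvalumab.

    ``discount_fraction`` may be given directly (the reported program-level
    average) or left ``None`` to be derived by enumerating paid versus free
    vials covering the monthly requirement.
    """

    vial_sizes_mg: tuple[float, ...] = (500.0, 120.0)
    discount_fraction: float | None = None

    def __post_init__(self):
        if self.discount_fraction is not None and not 0.0 <= self.discount_fraction < 1.0:
            raise ConfigurationError("discount_fraction must be in [0, 1)")


@dataclass
class CountryConfig:
    """One payer perspective: unit costs (USD), utilities, policy flags."""

    id: str
    currency_to_usd: float  # native currency units per 1 USD
    drug_prices: dict  # per-mg USD, or per-month USD for *_monthly drugs
    admin_cost_per_hour: float
    imaging_cost: float
    ihc_cost: float
    radiotherapy_cost: float
    monthly_bsc_cost: float
    death_cost_nsclc: float
    death_cost_other: float
    ae_unit_costs: dict
    wtp_per_qaly: float
    utilities: Utilities = field(default_factory=Utilities)
    discount_rate_annual: float = 0.03
    pdl1_gate: bool = False
    surveillance_interval_months: int = 3
    access_program: AccessProgram | None = None
    synthetic: bool = False  # emulated (non-published) cost table

    def __post_init__(self):
        if self.currency_to_usd <= 0:
            raise ConfigurationError("currency rate must be > 0")
        for name in (
            "admin_cost_per_hour",
            "imaging_cost",
            "ihc_cost",
            "radiotherapy_cost",
            "monthly_bsc_cost",
            "death_cost_nsclc",
            "death_cost_other",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for d, v in {**self.drug_prices, **self.ae_unit_costs}.items():
            if v < 0:
                raise ConfigurationError(f"negative cost for {d}")
        if self.discount_rate_annual < 0:
            raise ConfigurationError("discount rate must be >= 0")


@dataclass(frozen=True)
class DrugComponent:
    drug: str
    dose_rule: str  # per_kg | per_bsa | flat | flat_monthly | carboplatin_auc
    dose: float  # mg/kg, mg/m^2, mg, AUC target; unused for flat_monthly
    infusion_hours: float
    cycle_length_days: float
    max_cycles: int  # administrations (flat_monthly: months)

    def __post_init__(self):
        if self.max_cycles < 1:
            raise ConfigurationError("max_cycles must be >= 1")
        if self.infusion_hours < 0:
            raise ConfigurationError("infusion_hours must be >= 0")


@dataclass(frozen=True)
class Regimen:
    name: str
    components: tuple[DrugComponent, ...]
    ae_key: str


# Treatment catalog: dose sizes, schedules and maximum cycle counts per line.
REGIMENS: dict[str, Regimen] = {
    "durvalumab": Regimen(
        "durvalumab",
        (DrugComponent("durvalumab", "per_kg", 10.0, 1.0, 14.0, 24),),
        ae_key="durvalumab_arm",
    ),
    "pembrolizumab_combo_nonsquamous": Regimen(
        "pembrolizumab_combo_nonsquamous",
        (
            DrugComponent("pembrolizumab", "flat", 200.0, 0.5, 21.0, 31),
            DrugComponent("carboplatin", "carboplatin_auc", 5.0, 0.5, 21.0, 4),
            DrugComponent("pemetrexed", "per_bsa", 500.0, 0.17, 21.0, 31),
        ),
        ae_key="pembrolizumab_doublet",
    ),
    "pembrolizumab_combo_squamous": Regimen(
        "pembrolizumab_combo_squamous",
        (
            DrugComponent("pembrolizumab", "flat", 200.0, 0.5, 21.0, 31),
            DrugComponent("carboplatin", "carboplatin_auc", 5.0, 0.5, 21.0, 4),
            DrugComponent("nab_paclitaxel", "per_bsa", 200.0, 0.5, 21.0, 4),
        ),
        ae_key="pembrolizumab_doublet",
    ),
    "chemo_nonsquamous": Regimen(
        "chemo_nonsquamous",
        (
            DrugComponent("carboplatin", "carboplatin_auc", 5.0, 0.5, 21.0, 4),
            DrugComponent("pemetrexed", "per_bsa", 75.0, 0.17, 21.0, 29),
        ),
        ae_key="chemo_doublet",
    ),
    "chemo_squamous": Regimen(
        "chemo_squamous",
        (
            DrugComponent("carboplatin", "carboplatin_auc", 5.0, 0.5, 21.0, 4),
            DrugComponent("nab_paclitaxel", "per_bsa", 200.0, 0.5, 21.0, 4),
        ),
        ae_key="chemo_doublet",
    ),
    "osimertinib": Regimen(
        "osimertinib",
        (DrugComponent("osimertinib_monthly", "flat_monthly", 0.0, 0.0, 30.0, 36),),
        ae_key="osimertinib",
    ),
    "alectinib": Regimen(
        "alectinib",
        (DrugComponent("alectinib_monthly", "flat_monthly", 0.0, 0.0, 30.0, 36),),
        ae_key="alectinib",
    ),
    "docetaxel": Regimen(
        "docetaxel",
        (DrugComponent("docetaxel", "per_bsa", 75.0, 1.0, 21.0, 6),),
        ae_key="docetaxel",
    ),
}

# Grade 3-4 toxicity incidence per regimen, from each drug's pivotal phase 3
# trial.  The platinum-doublet-alone rates reuse the pembrolizumab-doublet
# table (control-arm rates are not tabulated separately).
AE_INCIDENCE: dict[str, dict[str, float]] = {
    "durvalumab_arm": {
        "fatigue": 0.002,
        "dyspnea": 0.015,
        "pneumonia": 0.044,
        "pneumonitis": 0.034,
        "diarrhea": 0.006,
        "anemia": 0.029,
    },
    "placebo_arm": {
        "fatigue": 0.013,
        "dyspnea": 0.026,
        "pneumonia": 0.038,
        "pneumonitis": 0.021,
        "diarrhea": 0.013,
        "anemia": 0.034,
    },
    "pembrolizumab_doublet": {
        "fatigue": 0.057,
        "diarrhea": 0.052,
        "neutropenia": 0.158,
        "dyspnea": 0.037,
        "anemia": 0.163,
    },
    "chemo_doublet": {
        "fatigue": 0.057,
        "diarrhea": 0.052,
        "neutropenia": 0.158,
        "dyspnea": 0.037,
        "anemia": 0.163,
    },
    "docetaxel": {
        "fatigue": 0.10,
        "diarrhea": 0.03,
        "dyspnea": 0.08,
        "stomatitis": 0.02,
        "vomiting": 0.02,
    },
    "osimertinib": {
        "diarrhea": 0.03,
        "fatigue": 0.01,
        "dyspnea": 0.01,
        "rash": 0.01,
        "anemia": 0.03,
    },
    "alectinib": {"anemia": 0.05, "rash": 0.01},
}


def creatinine_clearance(p: PatientProfile) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min), capped at 125."""
    if p.serum_creatinine is None or p.serum_creatinine <= 0:
        raise ConfigurationError("serum creatinine required for carboplatin dosing")
    crcl = ((140.0 - p.age) * p.weight) / (72.0 * p.serum_creatinine)
    if p.sex == FEMALE:
        crcl *= 0.85
    return min(crcl, CRCL_CAP_ML_MIN)


def dose_amount(component: DrugComponent, p: PatientProfile) -> float:
    """Dose in mg per administration for one regimen component."""
    rule = component.dose_rule
    if rule == "per_kg":
        return component.dose * p.weight
    if rule == "per_bsa":
        return component.dose * p.bsa
    if rule == "flat":
        return component.dose
    if rule == "carboplatin_auc":
        # Calvert formula: dose = AUC * (GFR + 25)
        return component.dose * (creatinine_clearance(p) + 25.0)
    if rule == "flat_monthly":
        raise ConfigurationError("flat_monthly components are priced per month, not per mg")
    raise ConfigurationError(f"unknown dose rule {rule!r}")


def discount_value(amount: float, month: float, annual_rate: float = 0.03) -> float:
    """Discount ``amount`` accrued at ``month`` back to time 0."""
    if annual_rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    return amount * (1.0 + annual_rate) ** (-month / 12.0)


def convert_currency(amount_native: float, config: CountryConfig) -> float:
    """Convert a native-currency amount to USD using the configured rate."""
    if config.currency_to_usd <= 0:
        raise ConfigurationError("currency rate must be > 0")
    return amount_native / config.currency_to_usd


def _price_for(drug: str, config: CountryConfig) -> float:
    try:
        return config.drug_prices[drug]
    except KeyError:
        raise ConfigurationError(
            f"no price for drug {drug!r} in country {config.id!r}"
        ) from None


def regimen_cost(
    regimen: Regimen,
    p: PatientProfile,
    months_on_treatment: float,
    config: CountryConfig,
    start_month: float = 0.0,
    discounting: bool = True,
) -> tuple[float, float]:
    """Discounted (acquisition, administration) cost of a treatment course.

    Administrations are delivered on the component's cycle schedule until
    either the time on treatment or the maximum cycle count runs out; each is
    discounted at its calendar month.
    """
    if months_on_treatment < 0:
        raise ValueError("months_on_treatment must be >= 0")
    rate = config.discount_rate_annual if discounting else 0.0
    acquisition = 0.0
    administration = 0.0
    for comp in regimen.components:
        price = _price_for(comp.drug, config)
        if comp.dose_rule == "flat_monthly":
            n_months = min(int(months_on_treatment), comp.max_cycles)
            for m in range(n_months):
                acquisition += discount_value(price, start_month + m, rate)
            continue
        n_admin = min(
            int(months_on_treatment * (DAYS_PER_MONTH / comp.cycle_length_days)),
            comp.max_cycles,
        )
        mg = dose_amount(comp, p)
        for j in range(n_admin):
            month = start_month + math.floor(j * comp.cycle_length_days / DAYS_PER_MONTH)
            acquisition += discount_value(mg * price, month, rate)
            administration += discount_value(
                comp.infusion_hours * config.admin_cost_per_hour, month, rate
            )
    return acquisition, administration


def adverse_event_cost(
    ae_key: str, config: CountryConfig, incidence_table: Mapping[str, Mapping[str, float]] | None = None
) -> float:
    """Expected one-time adverse-event cost at the start of a treatment line."""
    table = (incidence_table or AE_INCIDENCE).get(ae_key)
    if table is None:
        raise ConfigurationError(f"no adverse-event incidence table for {ae_key!r}")
    total = 0.0
    for tox, inc in table.items():
        if not 0.0 <= inc <= 1.0:
            raise ConfigurationError(f"incidence for {tox!r} outside [0, 1]")
        if tox not in config.ae_unit_costs:
            raise ConfigurationError(f"no unit cost for toxicity {tox!r} in {config.id!r}")
        total += inc * config.ae_unit_costs[tox]
    return total


def cost_trace(trace, p: PatientProfile, config: CountryConfig) -> dict:
    """Decomposed discounted USD cost of one simulated patient path.

    Components: diagnosis (entry imaging + IHC), pf_drug (chemoradiotherapy
    backbone for both arms plus durvalumab acquisition while progression
    free), postprog_drug (second-line regimen and docetaxel acquisition),
    administration (all infusion time), ae (expected adverse-event cost at
    the start of each treatment line), supportive (surveillance imaging while
    alive and best supportive care in POD2 after docetaxel ends), end_of_life
    (death cost by cause).  Drug and AE costs are discounted at the month a
    line starts or a dose is given; death costs at the end of the dying cycle.
    """
    rate = config.discount_rate_annual
    months_alive = trace.months_survived
    components = {k: 0.0 for k in (
        "diagnosis", "pf_drug", "postprog_drug", "administration", "ae",
        "supportive", "end_of_life",
    )}
    components["diagnosis"] = config.imaging_cost + config.ihc_cost
    components["pf_drug"] = config.radiotherapy_cost

    on_durvalumab = trace.effective_arm == "durvalumab"
    if on_durvalumab:
        acq, admin = regimen_cost(
            REGIMENS["durvalumab"], p, trace.months_in_pfs, config, start_month=0.0
        )
        components["pf_drug"] += acq
        components["administration"] += admin
    arm_ae_key = "durvalumab_arm" if on_durvalumab else "placebo_arm"
    components["ae"] += adverse_event_cost(arm_ae_key, config)

    if trace.progression1_month is not None and trace.months_in_pod1 >= 0:
        reg = REGIMENS[trace.regimen]
        start = float(trace.progression1_month)
        acq, admin = regimen_cost(reg, p, trace.months_in_pod1, config, start_month=start)
        components["postprog_drug"] += acq
        components["administration"] += admin
        components["ae"] += discount_value(adverse_event_cost(reg.ae_key, config), start, rate)

    if trace.progression2_month is not None:
        reg = REGIMENS["docetaxel"]
        start = float(trace.progression2_month)
        acq, admin = regimen_cost(reg, p, trace.months_in_pod2, config, start_month=start)
        components["postprog_drug"] += acq
        components["administration"] += admin
        components["ae"] += discount_value(adverse_event_cost(reg.ae_key, config), start, rate)
        # best supportive care once the docetaxel course (6 cycles q3w ~ 5 months) ends
        doc_months = math.ceil(6 * 21.0 / DAYS_PER_MONTH)
        for j in range(max(0, trace.months_in_pod2 - doc_months)):
            month = trace.progression2_month + doc_months + j
            components["supportive"] += discount_value(config.monthly_bsc_cost, month, rate)

    interval = config.surveillance_interval_months
    m = interval
    while m < months_alive:
        components["supportive"] += discount_value(config.imaging_cost, m, rate)
        m += interval

    if trace.death_month is not None:
        cost = config.death_cost_nsclc if trace.death_cause == "nsclc" else config.death_cost_other
        components["end_of_life"] = discount_value(cost, float(trace.death_month), rate)
    return components


def access_program_price_per_mg(
    list_price_per_mg: float,
    program: AccessProgram,
    p: PatientProfile | None = None,
    monthly_mg: float | None = None,
) -> float:
    """Effective per-mg durvalumab price under a vial-based access scheme."""
    if list_price_per_mg <= 0:
        raise ConfigurationError("list price must be > 0")
    frac = program.discount_fraction
    if frac is None:
        if monthly_mg is None:
            if p is None:
                raise ConfigurationError("a patient profile or monthly mg requirement is needed")
            monthly_mg = 10.0 * p.weight * (DAYS_PER_MONTH / 14.0)
        frac = _scheme_discount_fraction(monthly_mg, program.vial_sizes_mg)
    return list_price_per_mg * (1.0 - frac)


def _scheme_discount_fraction(monthly_mg: float, vial_sizes: tuple[float, ...]) -> float:
    """Paid-vs-dispensed enumeration: large vials in buy-1-get-2-free triplets,
    small vials on a buy-2-get-remainder-free basis for any remainder."""
    if monthly_mg <= 0:
        raise ConfigurationError("monthly requirement must be > 0")
    big = max(vial_sizes)
    small = min(vial_sizes)
    triplet = 3 * big
    n_triplets = int(monthly_mg // triplet)
    paid = n_triplets * big
    remainder = monthly_mg - n_triplets * triplet
    if remainder > 0:
        if len(vial_sizes) > 1 and small < big:
            n_small = math.ceil(remainder / small)
            paid_small = min(n_small, 2) * small
            paid += min(paid_small, big)  # one more paid big vial would also cover it
        else:
            paid += big
    if paid > monthly_mg:
        raise ConfigurationError(
            f"monthly requirement {monthly_mg} mg not coverable at a discount by vials {vial_sizes}"
        )
    return 1.0 - paid / monthly_mg
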