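"""Synthetic study inputs: calibrated survival curves and country cost tables.

The pipeline is exercised entirely offline.  First-line curves are
cure-mixture exponentials ``S(t) = c + (1 - c) * exp(-rho * t)`` sampled on a
monthly grid, with ``rho`` solved so the curve crosses 0.5 exactly at the
target median and the cure fraction chosen (within feasibility) to match the
trial's published five-year landmark survival.  Second- and third-line curves
are exponentials at the corresponding trials' median progression-free or
overall survival.  The US cost table is the published one; the Brazilian,
Singaporean and Spanish tables are transparent emulations (US structure,
rescaled prices) carrying every published anchor (PPP and exchange rates,
willingness-to-pay thresholds, the Singapore per-mg list price and access
program) verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .costing import AccessProgram, CountryConfig, Utilities
from .patients import PopulationPriors, US_PRIORS
from .simulate import ArmModel
from .survival import (
    CompositeSurvival,
    CurveValidationError,
    DigitizedCurve,
    exponential_survival,
    fit_composite,
)

__all__ = [
    "PlateauCurveSpec",
    "TrialBundle",
    "make_plateau_curve",
    "calibrate_cure_fraction",
    "make_country_config",
    "make_trial_bundle",
    "SCENARIOS",
    "LINE2_MEDIANS",
    "LINE3_OS_MEDIAN",
]

LN2 = math.log(2.0)

# Median time-to-progression on second-line therapy (months), from the pivotal
# trial of each regimen, and median OS on third-line docetaxel.
LINE2_MEDIANS = {
    "pembrolizumab_combo_nonsquamous": 8.8,
    "pembrolizumab_combo_squamous": 8.8,
    "chemo_nonsquamous": 4.9,
    "chemo_squamous": 4.9,
    "osimertinib": 18.9,
    "alectinib": 25.7,
}
LINE3_OS_MEDIAN = 10.5

# Published five-year landmark survival (time months, probability) used to pin
# the plateau of each first-line curve: OS 42.9%/33.4% and PFS 33.1%/19.0%
# for the immunotherapy and control arms of the registration trial.
_FIVE_YEAR_LANDMARKS = {
    ("durvalumab", "os"): (60.0, 0.429),
    ("placebo", "os"): (60.0, 0.334),
    ("durvalumab", "pfs"): (60.0, 0.331),
    ("placebo", "pfs"): (60.0, 0.190),
}

# displayed at-risk counts used for pseudo-IPD reconstruction (trial arm sizes)
_N_DISPLAY = {"durvalumab": 476, "placebo": 237}

_LAST_FOLLOWUP = 60.0

# The exponential tail of each first-line composite fit is estimated on the
# final year of follow-up (events / person-time on (t_f, last follow-up]),
# which is far more stable than the hazard of the single last KM interval.
_TAIL_WINDOW = 12.0


@dataclass(frozen=True)
class PlateauCurveSpec:
    target_median: float  # months
    cure_fraction: float
    last_followup: float
    n_display: int

    def __post_init__(self):
        if not 0.0 <= self.cure_fraction < 0.5:
            raise CurveValidationError(
                "cure_fraction must be in [0, 0.5) for the median to exist"
            )
        if not 0.0 < self.target_median < self.last_followup:
            raise CurveValidationError("target_median must lie within follow-up")
        if self.n_display < 1:
            raise CurveValidationError("n_display must be >= 1")


def _mixture_rate(median: float, cure: float) -> float:
    return -math.log((0.5 - cure) / (1.0 - cure)) / median


def make_plateau_curve(spec: PlateauCurveSpec) -> DigitizedCurve:
    """Cure-mixture exponential sampled monthly, crossing 0.5 at the target median."""
    rho = _mixture_rate(spec.target_median, spec.cure_fraction)
    grid = np.arange(0.0, spec.last_followup + 0.5, 1.0)
    surv = spec.cure_fraction + (1.0 - spec.cure_fraction) * np.exp(-rho * grid)
    return DigitizedCurve(
        times=tuple(grid), survival=tuple(surv), last_followup=spec.last_followup
    )


def calibrate_cure_fraction(
    median: float, landmark_time: float, landmark_survival: float
) -> float:
    """Cure fraction best matching a landmark survival, given an exact median.

    ``S_c(landmark_time)`` is increasing in ``c`` on [0, 0.5); the landmark is
    matched exactly when feasible and approached from below otherwise (a
    landmark below the pure-exponential value yields ``c = 0``).
    """
    grid = np.linspace(0.0, 0.499, 2000)
    vals = np.array(
        [c + (1 - c) * math.exp(-_mixture_rate(median, c) * landmark_time) for c in grid]
    )
    return float(grid[np.argmin(np.abs(vals - landmark_survival))])


# --- country configurations -------------------------------------------------

_US_DRUG_PRICES = {
    "durvalumab": 7.71,  # per mg
    "pembrolizumab": 53.7,
    "pemetrexed": 7.64,
    "carboplatin": 2.77 / 50.0,  # listed per 50 mg
    "docetaxel": 0.47,
    "nab_paclitaxel": 14.87,
    "osimertinib_monthly": 17079.18,  # per month
    "alectinib_monthly": 18160.67,
}

_US_AE_COSTS = {
    "fatigue": 16185.0,
    "dyspnea": 6018.0,
    "pneumonia": 9941.0,
    "diarrhea": 3265.0,
    "anemia": 4353.0,
    "pneumonitis": 9941.0,
    "neutropenia": 5321.0,
    "stomatitis": 1695.0,
    "vomiting": 895.0,
    "rash": 940.0,
}

# Emulated (non-published) country tables: US structure with one price scale
# for drugs and one for procedures/adverse events.  Published anchors (currency
# rates, WTP thresholds, the Singapore durvalumab list price and access scheme,
# the Spanish PD-L1 reimbursement gate) are carried verbatim.
_COUNTRY_SCALES = {
    "BR": {"drug": 0.62, "other": 0.88, "rate": 2.53, "wtp": 22251.0},
    "SG": {"drug": 0.67, "other": 0.75, "rate": 1.34, "wtp": 55288.0},
    "ES": {"drug": 0.62, "other": 1.00, "rate": 0.90, "wtp": 107069.0},
}

_SG_DURVALUMAB_LIST_PER_MG = 6.38
_SG_ACCESS_DISCOUNT = 0.337


def make_country_config(country_id: str) -> CountryConfig:
    """Cost/utility/policy configuration for one of US, BR, SG, ES."""
    if country_id == "US":
        return CountryConfig(
            id="US",
            currency_to_usd=1.0,
            drug_prices=dict(_US_DRUG_PRICES),
            admin_cost_per_hour=205.43,
            imaging_cost=2045.91,
            ihc_cost=141.4,
            radiotherapy_cost=2036.3,
            monthly_bsc_cost=80.91,
            death_cost_nsclc=13273.0,
            death_cost_other=10492.0,
            ae_unit_costs=dict(_US_AE_COSTS),
            wtp_per_qaly=150000.0,
            utilities=Utilities(),
        )
    if country_id not in _COUNTRY_SCALES:
        raise ValueError(f"unknown country {country_id!r}; expected US, BR, SG or ES")
    s = _COUNTRY_SCALES[country_id]
    drug_prices = {k: v * s["drug"] for k, v in _US_DRUG_PRICES.items()}
    if country_id == "SG":
        drug_prices["durvalumab"] = _SG_DURVALUMAB_LIST_PER_MG
    return CountryConfig(
        id=country_id,
        currency_to_usd=s["rate"],
        drug_prices=drug_prices,
        admin_cost_per_hour=205.43 * s["other"],
        imaging_cost=2045.91 * s["other"],
        ihc_cost=141.4 * s["other"],
        radiotherapy_cost=2036.3 * s["other"],
        monthly_bsc_cost=80.91 * s["other"],
        death_cost_nsclc=13273.0 * s["other"],
        death_cost_other=10492.0 * s["other"],
        ae_unit_costs={k: v * s["other"] for k, v in _US_AE_COSTS.items()},
        wtp_per_qaly=s["wtp"],
        utilities=Utilities(),
        pdl1_gate=(country_id == "ES"),
        access_program=(
            AccessProgram(discount_fraction=_SG_ACCESS_DISCOUNT) if country_id == "SG" else None
        ),
        synthetic=True,
    )


# --- scenario bundles -------------------------------------------------------

# arm medians (months): {endpoint: {arm: median}}
SCENARIOS = {
    "us_base": {
        "country": "US",
        "os": {"durvalumab": 51.1, "placebo": 39.3},
        "pfs": {"durvalumab": 37.9, "placebo": 19.9},
    },
    "pooled": {
        "country": "US",
        "os": {"durvalumab": 45.0, "placebo": 37.4},
        "pfs": {"durvalumab": 31.9, "placebo": 19.9},
    },
    "spain_gated": {
        "country": "ES",
        "os": {"durvalumab": 50.8, "placebo": 38.4},
        "pfs": {"durvalumab": 37.9, "placebo": 19.9},
    },
    "singapore_access": {
        "country": "SG",
        "os": {"durvalumab": 53.1, "placebo": 42.0},
        "pfs": {"durvalumab": 37.9, "placebo": 19.9},
    },
}

# Biomarker priors per country; Singapore EGFR 43.4% and Spain ALK 11% are
# published figures, the Brazilian EGFR excess is an emulation.
_COUNTRY_PRIORS = {
    "US": US_PRIORS,
    "BR": replace(US_PRIORS, egfr_fraction=0.25, alk_fraction=0.02),
    "SG": replace(US_PRIORS, egfr_fraction=0.434, alk_fraction=0.05),
    "ES": replace(US_PRIORS, egfr_fraction=0.06, alk_fraction=0.11),
}


@dataclass
class TrialBundle:
    """Everything a run needs: curves, arm models, priors and country config."""

    scenario: str
    seed: int
    curves: dict  # (arm, endpoint) -> DigitizedCurve
    arm_models: dict  # arm -> ArmModel
    priors: PopulationPriors
    config: CountryConfig
    n_display: dict = field(default_factory=lambda: dict(_N_DISPLAY))


def make_trial_bundle(scenario: str, seed: int = 0) -> TrialBundle:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}")
    spec = SCENARIOS[scenario]
    config = make_country_config(spec["country"])
    if scenario == "singapore_access":
        from .costing import access_program_price_per_mg

        config.drug_prices["durvalumab"] = access_program_price_per_mg(
            config.drug_prices["durvalumab"], config.access_program
        )
    curves = {}
    firstline = {}
    for arm in ("durvalumab", "placebo"):
        for endpoint in ("pfs", "os"):
            median = spec[endpoint][arm]
            lm_time, lm_surv = _FIVE_YEAR_LANDMARKS[(arm, endpoint)]
            cure = calibrate_cure_fraction(median, lm_time, lm_surv)
            curve = make_plateau_curve(
                PlateauCurveSpec(
                    target_median=median,
                    cure_fraction=cure,
                    last_followup=_LAST_FOLLOWUP,
                    n_display=_N_DISPLAY[arm],
                )
            )
            curves[(arm, endpoint)] = curve
            firstline[(arm, endpoint)] = fit_composite(
                curve, assumed_n=_N_DISPLAY[arm], t_f=_LAST_FOLLOWUP - _TAIL_WINDOW
            )
    line2 = {name: exponential_survival(LN2 / med) for name, med in LINE2_MEDIANS.items()}
    line3 = exponential_survival(LN2 / LINE3_OS_MEDIAN)
    arm_models = {
        arm: ArmModel(
            pfs_curve=firstline[(arm, "pfs")],
            os_curve=firstline[(arm, "os")],
            line2_ttp_curves=dict(line2),
            line3_os_curve=line3,
        )
        for arm in ("durvalumab", "placebo")
    }
    return TrialBundle(
        scenario=scenario,
        seed=seed,
        curves=curves,
        arm_models=arm_models,
        priors=_COUNTRY_PRIORS[spec["country"]],
        config=config,
    )
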