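"""One place that wires generation, simulation, accrual and summaries together.

``ScenarioParams`` is the full parameter vector a sensitivity analysis can
perturb: the country configuration plus multiplicative factors on the
extrapolation tail rates of the four first-line curves.  ``run_cea`` executes
the whole pipeline for one parameter vector; sensitivity analyses call it
through ``make_model_runner`` with bootstrap disabled.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .costing import CountryConfig
from .outcomes import CEAResult, accrue_patient_outcomes, compute_icer, summarize_cea
from .patients import generate_patients
from .simulate import ArmModel, simulate_cohort
from .synthetic import TrialBundle

__all__ = ["ScenarioParams", "QuickResult", "run_cea", "make_model_runner"]

TAIL_KEYS = ("durvalumab_pfs", "durvalumab_os", "placebo_pfs", "placebo_os")


@dataclass
class ScenarioParams:
    config: CountryConfig
    tail_multipliers: dict = field(
        default_factory=lambda: {k: 1.0 for k in TAIL_KEYS}
    )

    @classmethod
    def from_bundle(cls, bundle: TrialBundle) -> "ScenarioParams":
        cfg = copy.deepcopy(bundle.config)
        if cfg.utilities.pfs_durvalumab is None:
            # materialize the arm-specific utility so analyses can vary it alone
            cfg.utilities.pfs_durvalumab = cfg.utilities.pfs
        return cls(config=cfg)


@dataclass
class QuickResult:
    """Point estimates of a single model run (no bootstrap)."""

    delta_cost: float
    delta_qaly: float
    delta_life_years: float
    icer: float
    arm_qalys: dict
    arm_costs: dict


def _apply_tail_multipliers(arm_models: dict, mult: dict) -> dict:
    out = {}
    for arm, model in arm_models.items():
        out[arm] = ArmModel(
            pfs_curve=replace(
                model.pfs_curve, tail_rate=model.pfs_curve.tail_rate * mult[f"{arm}_pfs"]
            ),
            os_curve=replace(
                model.os_curve, tail_rate=model.os_curve.tail_rate * mult[f"{arm}_os"]
            ),
            line2_ttp_curves=model.line2_ttp_curves,
            line3_os_curve=model.line3_os_curve,
        )
    return out


def run_cea(
    bundle: TrialBundle,
    params: ScenarioParams | None = None,
    n_patients: int = 1000,
    horizon_cycles: int = 120,
    seed: int = 0,
    n_boot: int = 1000,
    pod1_death_mode: str = "calibrated",
):
    """Full pipeline for one parameter vector.

    Returns a :class:`CEAResult` when ``n_boot > 0``, else a lighter
    :class:`QuickResult` with point estimates only.
    """
    if params is None:
        params = ScenarioParams.from_bundle(bundle)
    config = params.config
    patients = generate_patients(n_patients, bundle.priors, seed=seed)
    arm_models = _apply_tail_multipliers(bundle.arm_models, params.tail_multipliers)
    traces = simulate_cohort(
        patients,
        arm_models,
        config,
        horizon_cycles=horizon_cycles,
        seed=seed,
        pod1_death_mode=pod1_death_mode,
    )
    outcomes = {
        arm: [accrue_patient_outcomes(tr, p, config) for tr, p in zip(trs, patients)]
        for arm, trs in traces.items()
    }
    if n_boot > 0:
        return summarize_cea(outcomes, traces, n_boot=n_boot, seed=seed)
    d, p = outcomes["durvalumab"], outcomes["placebo"]
    mean = lambda xs: float(np.mean(xs))
    dc = mean([o.total_cost for o in d]) - mean([o.total_cost for o in p])
    dq = mean([o.qalys for o in d]) - mean([o.qalys for o in p])
    dly = mean([o.life_years for o in d]) - mean([o.life_years for o in p])
    return QuickResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_life_years=dly,
        icer=compute_icer(dc, dq).value,
        arm_qalys={"durvalumab": mean([o.qalys for o in d]), "placebo": mean([o.qalys for o in p])},
        arm_costs={
            "durvalumab": mean([o.total_cost for o in d]),
            "placebo": mean([o.total_cost for o in p]),
        },
    )


def make_model_runner(
    bundle: TrialBundle,
    n_patients: int = 1000,
    horizon_cycles: int = 120,
    seed: int = 0,
    pod1_death_mode: str = "calibrated",
):
    """Callable ``params -> QuickResult`` reusing one fixed cohort seed.

    The same master seed (hence the same patients and event uniforms) is used
    for every call — common random numbers across parameter draws — so
    sensitivity analyses see parameter effects, not Monte-Carlo noise.
    """

    def runner(params: ScenarioParams) -> QuickResult:
        return run_cea(
            bundle,
            params=params,
            n_patients=n_patients,
            horizon_cycles=horizon_cycles,
            seed=seed,
            n_boot=0,
            pod1_death_mode=pod1_death_mode,
        )

    return runner
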