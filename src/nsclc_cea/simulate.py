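"""Four-state monthly microsimulation: PFS -> POD1 -> POD2 -> death.

Transition bookkeeping
----------------------
* From PFS, the monthly death probability comes from the first-line OS curve
  and the progression probability is the residual of the first-line PFS event
  probability after death (floored at 0 and conditioned on surviving the
  cycle), so simulated progression-free survival and pre-progression death
  both track their configured marginal curves.
* From POD1, time to second progression follows the assigned regimen's
  second-line curve (clock restarted at POD1 entry).
* Post-progression mortality is reconciled with the first-line OS curve to
  avoid double counting (the source OS curve already contains all
  post-progression deaths).  In the default ``calibrated`` mode, each cycle's
  death budget is the first-line OS hazard applied to the whole surviving
  cohort; PFS occupants always die at the OS hazard, POD2 occupants die at
  the third-line OS hazard scaled down if it would overdraw the budget, and
  the residual is allocated to POD1 occupants.  Overall survival then tracks
  the first-line OS curve while the third-line curve shapes how mortality is
  distributed over post-progression states.  Mode ``residual`` never scales
  the third-line hazard (POD2 may overdraw the budget), and ``os_hazard``
  applies the raw OS hazard in POD1 and the third-line hazard in POD2 with no
  reconciliation.
* A patient whose first and second progressions fall in the same cycle
  records a direct PFS -> POD2 transition.

Each patient owns an RNG stream derived from ``(seed, patient index)``; the
same streams are replayed for both strategies (common random numbers), and
cohort-size changes never reshuffle earlier patients.  Every event process
(death, first progression, second progression) is driven by a single
persistent uniform per patient, crossed by the running product of that
process's per-cycle survival probabilities.  Cycle by cycle this applies
exactly the same conditional monthly probabilities as fresh per-cycle draws
— the per-patient marginals are identical — but it couples the two strategy
arms comonotonically, which sharply reduces Monte-Carlo noise on incremental
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patients import PatientProfile, apply_country_policy, assign_pod1_regimen
from .survival import CompositeSurvival, monthly_transition_probs

__all__ = ["ArmModel", "StateTrace", "simulate_cohort", "simulate_arm", "PFS", "POD1", "POD2", "DEATH"]

PFS, POD1, POD2, DEATH = 0, 1, 2, 3
_STATE_ORDER = {PFS: 0, POD1: 1, POD2: 2, DEATH: 3}


@dataclass(frozen=True)
class ArmModel:
    """Survival inputs for one strategy arm."""

    pfs_curve: CompositeSurvival
    os_curve: CompositeSurvival
    line2_ttp_curves: dict  # regimen name -> CompositeSurvival
    line3_os_curve: CompositeSurvival


@dataclass
class StateTrace:
    """One simulated patient's path through the model."""

    arm: str
    effective_arm: str
    states: np.ndarray  # state occupied during each cycle (length = horizon)
    regimen: str  # POD1 regimen assigned at generation time
    progression1_month: int | None = None
    progression2_month: int | None = None
    death_month: int | None = None
    death_cause: str | None = None  # "nsclc" | "other"
    horizon: int = 120

    @property
    def months_survived(self) -> int:
        return self.death_month if self.death_month is not None else self.horizon

    @property
    def months_in_pfs(self) -> int:
        first_exit = [m for m in (self.progression1_month, self.death_month) if m is not None]
        return min(first_exit) if first_exit else self.horizon

    @property
    def months_in_pod1(self) -> int:
        if self.progression1_month is None:
            return 0
        ends = [m for m in (self.progression2_month, self.death_month) if m is not None]
        end = min(ends) if ends else self.horizon
        return end - self.progression1_month

    @property
    def months_in_pod2(self) -> int:
        if self.progression2_month is None:
            return 0
        end = self.death_month if self.death_month is not None else self.horizon
        return end - self.progression2_month


def _validate_arm_model(model: ArmModel, regimens: set[str]):
    missing = regimens - set(model.line2_ttp_curves)
    if missing:
        raise ValueError(f"no second-line curve configured for regimen(s): {sorted(missing)}")


def simulate_cohort(
    patients: list[PatientProfile],
    arm_models: dict,
    country,
    horizon_cycles: int = 120,
    seed: int = 0,
    pod1_death_mode: str = "calibrated",
) -> dict:
    """Run both strategy arms over the same patients; returns arm -> traces."""
    return {
        arm: simulate_arm(
            patients,
            arm,
            arm_models,
            country,
            horizon_cycles=horizon_cycles,
            seed=seed,
            pod1_death_mode=pod1_death_mode,
        )
        for arm in ("durvalumab", "placebo")
    }


def simulate_arm(
    patients: list[PatientProfile],
    arm: str,
    arm_models: dict,
    country,
    horizon_cycles: int = 120,
    seed: int = 0,
    pod1_death_mode: str = "calibrated",
) -> list[StateTrace]:
    if horizon_cycles < 1:
        raise ValueError("horizon must be >= 1")
    if pod1_death_mode not in ("calibrated", "residual", "os_hazard"):
        raise ValueError(f"unknown pod1_death_mode {pod1_death_mode!r}")
    n = len(patients)
    H = horizon_cycles

    regimen_names = [assign_pod1_regimen(p) for p in patients]
    eff_arms = [apply_country_policy(p, arm, country) for p in patients]
    for a in ("durvalumab", "placebo"):
        if a in (arm, *eff_arms):
            _validate_arm_model(arm_models[a], set(regimen_names))

    if n == 0:
        return []

    # monthly probability tables, indexed by effective arm and regimen
    arm_keys = ["durvalumab", "placebo"]
    p_os = np.stack([monthly_transition_probs(arm_models[a].os_curve, H) for a in arm_keys])
    p_pfs_event = np.stack(
        [monthly_transition_probs(arm_models[a].pfs_curve, H) for a in arm_keys]
    )
    # progression probability conditional on surviving the cycle
    with np.errstate(divide="ignore", invalid="ignore"):
        p_prog = np.clip(
            np.where(p_os < 1.0, (p_pfs_event - p_os) / (1.0 - p_os), 0.0), 0.0, 1.0
        )
    reg_index = {}
    p_line2_rows = []
    for a in arm_keys:
        for name, curve in arm_models[a].line2_ttp_curves.items():
            key = (a, name)
            if key not in reg_index:
                reg_index[key] = len(p_line2_rows)
                p_line2_rows.append(monthly_transition_probs(curve, H))
    p_line2 = np.stack(p_line2_rows)
    p_line3 = np.stack(
        [monthly_transition_probs(arm_models[a].line3_os_curve, H) for a in arm_keys]
    )

    eff_idx = np.array([0 if a == "durvalumab" else 1 for a in eff_arms])
    reg_idx = np.array([reg_index[(eff_arms[i], regimen_names[i])] for i in range(n)])

    # one persistent uniform per patient per event process
    V = np.empty((n, 3))
    base = int(seed) % (2**31)
    for i in range(n):
        V[i] = np.random.default_rng([base, 7919, i]).random(3)
    v_death, v_prog, v_line2 = V[:, 0], V[:, 1], V[:, 2]
    cum_death = np.ones(n)  # whole-life death process
    cum_prog = np.ones(n)  # first-progression process
    cum_l2 = np.ones(n)  # second-progression process

    state = np.zeros(n, dtype=np.int8)
    entry1 = np.full(n, -1, dtype=np.int32)  # cycle during which POD1 was entered
    entry2 = np.full(n, -1, dtype=np.int32)
    prog1_m = np.full(n, -1, dtype=np.int32)
    prog2_m = np.full(n, -1, dtype=np.int32)
    death_m = np.full(n, -1, dtype=np.int32)
    cause = np.zeros(n, dtype=np.int8)  # 0 none, 1 nsclc, 2 other
    states_hist = np.full((n, H), DEATH, dtype=np.int8)

    for t in range(H):
        alive = state != DEATH
        if not alive.any():
            break
        states_hist[alive, t] = state[alive]
        in_pfs = state == PFS
        in_pod1 = state == POD1
        in_pod2 = state == POD2

        p_death_i = np.zeros(n)
        p_death_i[in_pfs] = p_os[eff_idx[in_pfs], t]
        if in_pod2.any():
            age2 = np.minimum(t - entry2[in_pod2] - 1, H - 1)
            age2 = np.maximum(age2, 0)
            p_death_i[in_pod2] = p_line3[eff_idx[in_pod2], age2]
        if pod1_death_mode in ("calibrated", "residual"):
            budget = float(np.sum(p_os[eff_idx[alive], t]))
            spent_pfs = float(np.sum(p_death_i[in_pfs]))
            spent_pod2 = float(np.sum(p_death_i[in_pod2]))
            if (
                pod1_death_mode == "calibrated"
                and in_pod2.any()
                and spent_pfs + spent_pod2 > budget
            ):
                scale = max(budget - spent_pfs, 0.0) / spent_pod2
                p_death_i[in_pod2] *= scale
                spent_pod2 = max(budget - spent_pfs, 0.0)
            if in_pod1.any():
                p_resid = (budget - spent_pfs - spent_pod2) / int(in_pod1.sum())
                p_death_i[in_pod1] = min(max(p_resid, 0.0), 1.0)
        elif in_pod1.any():
            p_death_i[in_pod1] = p_os[eff_idx[in_pod1], t]

        cum_death_new = np.where(alive, cum_death * (1.0 - p_death_i), cum_death)
        dies = alive & (v_death > cum_death_new)
        cum_death = cum_death_new
        death_m[dies] = t + 1
        cause[dies] = np.where(state[dies] == PFS, 2, 1)
        state[dies] = DEATH

        # progression among cycle survivors
        surv_pfs = in_pfs & ~dies
        if surv_pfs.any():
            cum_prog[surv_pfs] *= 1.0 - p_prog[eff_idx[surv_pfs], t]
            progresses = surv_pfs & (v_prog > cum_prog)
            if progresses.any():
                prog1_m[progresses] = t + 1
                entry1[progresses] = t
                state[progresses] = POD1
                # same-cycle second progression: direct PFS -> POD2
                cum_l2[progresses] *= 1.0 - p_line2[reg_idx[progresses], 0]
                direct = progresses & (v_line2 > cum_l2)
                if direct.any():
                    prog2_m[direct] = t + 1
                    entry2[direct] = t
                    state[direct] = POD2
        surv_pod1 = in_pod1 & ~dies
        if surv_pod1.any():
            age1 = np.maximum(np.minimum(t - entry1[surv_pod1] - 1, H - 1), 0)
            cum_l2[surv_pod1] *= 1.0 - p_line2[reg_idx[surv_pod1], age1]
            progresses2 = surv_pod1 & (v_line2 > cum_l2)
            if progresses2.any():
                prog2_m[progresses2] = t + 1
                entry2[progresses2] = t
                state[progresses2] = POD2

    traces = []
    for i in range(n):
        traces.append(
            StateTrace(
                arm=arm,
                effective_arm=eff_arms[i],
                states=states_hist[i],
                regimen=regimen_names[i],
                progression1_month=int(prog1_m[i]) if prog1_m[i] >= 0 else None,
                progression2_month=int(prog2_m[i]) if prog2_m[i] >= 0 else None,
                death_month=int(death_m[i]) if death_m[i] >= 0 else None,
                death_cause={0: None, 1: "nsclc", 2: "other"}[int(cause[i])],
                horizon=H,
            )
        )
    return traces
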