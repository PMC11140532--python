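"""Per-patient outcome accrual and arm-level cost-effectiveness summaries.

Quality-adjusted life-years and life-years are accrued at the end of each
monthly cycle (1/12 of a year weighted by the occupied state's utility,
discounted at that month); the cycle in which death occurs accrues nothing.
Arm summaries are means over simulated patients with nonparametric percentile
bootstrap confidence intervals; median progression-free and overall survival
are Kaplan-Meier medians of the simulated event times (censored at the
horizon), with linear interpolation at the 0.5 crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .costing import CountryConfig, cost_trace
from .patients import PatientProfile
from .simulate import PFS, StateTrace

__all__ = [
    "PatientOutcome",
    "ICERResult",
    "Estimate",
    "CEAResult",
    "accrue_patient_outcomes",
    "compute_icer",
    "summarize_cea",
    "km_median",
]

COST_COMPONENTS = (
    "diagnosis",
    "pf_drug",
    "postprog_drug",
    "administration",
    "ae",
    "supportive",
    "end_of_life",
)


@dataclass
class PatientOutcome:
    life_years: float
    qalys: float
    cost_components: dict
    total_cost: float

    def __post_init__(self):
        if abs(self.total_cost - sum(self.cost_components.values())) > 1e-6:
            raise ValueError("total cost does not equal the sum of its components")


def accrue_patient_outcomes(
    trace: StateTrace, p: PatientProfile, config: CountryConfig
) -> PatientOutcome:
    """Discounted QALYs, life-years and decomposed costs for one patient."""
    rate = config.discount_rate_annual
    # the dying cycle accrues no occupancy (end-of-cycle evaluation)
    n_acc = trace.months_survived - (1 if trace.death_month is not None else 0)
    n_acc = max(n_acc, 0)
    months = np.arange(1, n_acc + 1, dtype=float)
    disc = (1.0 + rate) ** (-months / 12.0)
    u_pfs = config.utilities.pfs_for_arm(trace.effective_arm)
    u = np.where(trace.states[:n_acc] == PFS, u_pfs, config.utilities.pod)
    qalys = float((u * disc).sum() / 12.0)
    life_years = float(disc.sum() / 12.0)
    components = cost_trace(trace, p, config)
    return PatientOutcome(
        life_years=life_years,
        qalys=qalys,
        cost_components=components,
        total_cost=sum(components.values()),
    )


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness ratio with dominance classification."""

    value: float  # USD per unit effect; NaN when the ratio is undefined
    classification: str  # "ratio" | "dominant" | "dominated" | "undefined"


def compute_icer(delta_cost: float, delta_effect: float) -> ICERResult:
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise ValueError("incremental cost and effect must be finite")
    if delta_effect > 0:
        value = delta_cost / delta_effect
        return ICERResult(value, "dominant" if delta_cost < 0 else "ratio")
    if delta_cost > 0:
        return ICERResult(float("nan"), "dominated")
    return ICERResult(float("nan"), "undefined")


def km_median(durations, events) -> float:
    """Kaplan-Meier median with linear interpolation at the 0.5 crossing."""
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - start
    d = np.add.reduceat(e, start)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    prev_t, prev_v = 0.0, 1.0
    for ti, vi in zip(uniq, surv):
        if vi <= 0.5:
            if prev_v == vi:
                return float(ti)
            return float(prev_t + (prev_v - 0.5) / (prev_v - vi) * (ti - prev_t))
        prev_t, prev_v = float(ti), float(vi)
    return math.inf


def _pfs_time(trace: StateTrace) -> tuple[float, int]:
    m = trace.months_in_pfs
    return float(m), int(m < trace.horizon)


def _os_time(trace: StateTrace) -> tuple[float, int]:
    return float(trace.months_survived), int(trace.death_month is not None)


@dataclass(frozen=True)
class Estimate:
    value: float
    lo: float = float("nan")
    hi: float = float("nan")


@dataclass
class CEAResult:
    """Per-arm and incremental summaries with 95% bootstrap CIs."""

    arms: dict  # arm -> {field: Estimate}
    incremental: dict  # field -> Estimate
    icer_per_qaly: Estimate
    icer_classification: str
    incremental_cost_per_life_year: Estimate
    n_patients: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        def est(e):
            return {"value": e.value, "ci_lo": e.lo, "ci_hi": e.hi}

        return {
            "n_patients": self.n_patients,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "arms": {a: {f: est(e) for f, e in d.items()} for a, d in self.arms.items()},
            "incremental": {f: est(e) for f, e in self.incremental.items()},
            "icer_per_qaly": est(self.icer_per_qaly),
            "icer_classification": self.icer_classification,
            "incremental_cost_per_life_year": est(self.incremental_cost_per_life_year),
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        fields = next(iter(self.arms.values())).keys()
        for f in fields:
            row = {"endpoint": f}
            for a in self.arms:
                e = self.arms[a][f]
                row[a] = e.value
                row[f"{a}_ci"] = f"({e.lo:.1f} to {e.hi:.1f})"
            inc = self.incremental[f]
            row["incremental"] = inc.value
            row["incremental_ci"] = f"({inc.lo:.1f} to {inc.hi:.1f})"
            rows.append(row)
        return pd.DataFrame(rows)


_MEAN_FIELDS = ("total_cost", "drug_cost", "pf_drug_cost", "postprog_drug_cost", "ae_cost", "qalys", "life_years")
_MEDIAN_FIELDS = ("median_pfs", "median_os")


def summarize_cea(
    outcomes: dict,
    traces: dict,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> CEAResult:
    """Table-style summary of a two-arm run.

    ``outcomes``/``traces`` map arm name -> per-patient lists (both arms run
    over the same patients, so the bootstrap resamples patient indices jointly
    across arms).  The incremental cost per life-year follows the source
    convention of dividing by the incremental *median* OS expressed in years.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    arms = list(outcomes)
    if len(arms) != 2 or any(not outcomes[a] for a in arms):
        raise ValueError("two nonempty arms are required")
    n = len(outcomes[arms[0]])
    if any(len(outcomes[a]) != n or len(traces[a]) != n for a in arms):
        raise ValueError("arms must contain the same patients")

    data = {}
    for a in arms:
        cols = {
            "total_cost": np.array([o.total_cost for o in outcomes[a]]),
            "pf_drug_cost": np.array([o.cost_components["pf_drug"] for o in outcomes[a]]),
            "postprog_drug_cost": np.array(
                [o.cost_components["postprog_drug"] for o in outcomes[a]]
            ),
            "ae_cost": np.array([o.cost_components["ae"] for o in outcomes[a]]),
            "qalys": np.array([o.qalys for o in outcomes[a]]),
            "life_years": np.array([o.life_years for o in outcomes[a]]),
        }
        cols["drug_cost"] = cols["pf_drug_cost"] + cols["postprog_drug_cost"]
        cols["pfs_t"], cols["pfs_e"] = map(
            np.array, zip(*[_pfs_time(tr) for tr in traces[a]])
        )
        cols["os_t"], cols["os_e"] = map(np.array, zip(*[_os_time(tr) for tr in traces[a]]))
        data[a] = cols

    def stats(idx):
        out = {}
        for a in arms:
            c = data[a]
            s = {f: float(c[f][idx].mean()) for f in _MEAN_FIELDS}
            s["median_pfs"] = km_median(c["pfs_t"][idx], c["pfs_e"][idx])
            s["median_os"] = km_median(c["os_t"][idx], c["os_e"][idx])
            out[a] = s
        inc = {f: out[arms[0]][f] - out[arms[1]][f] for f in _MEAN_FIELDS + _MEDIAN_FIELDS}
        return out, inc

    full_idx = np.arange(n)
    point, point_inc = stats(full_idx)

    rng = np.random.default_rng([int(seed) % (2**31), 104729])
    boot_arm = {a: {f: [] for f in _MEAN_FIELDS + _MEDIAN_FIELDS} for a in arms}
    boot_inc = {f: [] for f in _MEAN_FIELDS + _MEDIAN_FIELDS}
    boot_icer, boot_cply = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        b, binc = stats(idx)
        for a in arms:
            for f, v in b[a].items():
                boot_arm[a][f].append(v)
        for f, v in binc.items():
            boot_inc[f].append(v)
        if binc["qalys"] > 0:
            boot_icer.append(binc["total_cost"] / binc["qalys"])
        if binc["median_os"] > 0 and math.isfinite(binc["median_os"]):
            boot_cply.append(binc["total_cost"] / (binc["median_os"] / 12.0))

    alpha = (1.0 - ci_level) / 2.0

    def ci(samples):
        s = np.asarray(samples, dtype=float)
        s = s[np.isfinite(s)]
        if len(s) == 0:
            return float("nan"), float("nan")
        return float(np.quantile(s, alpha)), float(np.quantile(s, 1.0 - alpha))

    arms_out = {
        a: {f: Estimate(point[a][f], *ci(boot_arm[a][f])) for f in _MEAN_FIELDS + _MEDIAN_FIELDS}
        for a in arms
    }
    inc_out = {f: Estimate(point_inc[f], *ci(boot_inc[f])) for f in _MEAN_FIELDS + _MEDIAN_FIELDS}
    icer = compute_icer(point_inc["total_cost"], point_inc["qalys"])
    icer_est = Estimate(icer.value, *ci(boot_icer))
    if point_inc["median_os"] > 0 and math.isfinite(point_inc["median_os"]):
        cply = point_inc["total_cost"] / (point_inc["median_os"] / 12.0)
    else:
        cply = float("nan")
    return CEAResult(
        arms=arms_out,
        incremental=inc_out,
        icer_per_qaly=icer_est,
        icer_classification=icer.classification,
        incremental_cost_per_life_year=Estimate(cply, *ci(boot_cply)),
        n_patients=n,
        n_boot=n_boot,
        seed=seed,
    )
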