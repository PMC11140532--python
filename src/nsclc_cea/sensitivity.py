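"""Deterministic and probabilistic sensitivity analysis.

One-way analyses vary a single parameter to its low and high value with all
else at base and rank parameters by outcome spread (tornado order).  The
probabilistic analysis draws full parameter vectors from per-parameter
distributions (beta for utilities, gamma for costs, lognormal multipliers on
survival-tail rates — standard health-technology-assessment conventions, as
the source analysis does not state its distributions), pushes each draw
through the full model, and summarizes cost-effectiveness acceptability
against willingness-to-pay thresholds.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .runner import ScenarioParams

__all__ = [
    "DSAEntry",
    "PSADraw",
    "Distribution",
    "one_way_dsa",
    "run_psa",
    "ceac_curve",
    "default_dsa_ranges",
    "default_psa_distributions",
    "get_param",
    "set_param",
]


def _resolve(obj, path: str, create_missing: bool = False):
    parts = path.split(".")
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj, parts[-1]


def get_param(params, path: str) -> float:
    obj, leaf = _resolve(params, path)
    return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)


def set_param(params, path: str, value: float) -> None:
    obj, leaf = _resolve(params, path)
    if isinstance(obj, dict):
        obj[leaf] = value
    else:
        setattr(obj, leaf, value)


@dataclass(frozen=True)
class DSAEntry:
    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float
    spread: float


def one_way_dsa(
    base_params: ScenarioParams,
    param_ranges: dict,
    model_runner,
    metric: str = "delta_qaly",
) -> list[DSAEntry]:
    """Vary each parameter alone to its bounds; return entries sorted by spread."""
    entries = []
    for path, (lo, hi) in param_ranges.items():
        base = get_param(base_params, path)
        if not (min(lo, hi) <= base <= max(lo, hi)):
            raise ValueError(
                f"range ({lo}, {hi}) for {path!r} does not bracket base value {base}"
            )
        outs = []
        for v in (lo, hi):
            trial = copy.deepcopy(base_params)
            set_param(trial, path, v)
            outs.append(getattr(model_runner(trial), metric))
        entries.append(
            DSAEntry(
                parameter=path,
                low=lo,
                high=hi,
                outcome_low=outs[0],
                outcome_high=outs[1],
                spread=abs(outs[1] - outs[0]),
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


@dataclass(frozen=True)
class Distribution:
    """PSA input distribution, parameterized by mean and standard error."""

    kind: str  # "beta" | "gamma" | "lognormal_multiplier" | "point"
    mean: float
    se: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.mean
        if self.se <= 0:
            raise ValueError(f"{self.kind} distribution needs se > 0")
        if self.kind == "beta":
            m, v = self.mean, self.se**2
            if not 0 < m < 1 or v >= m * (1 - m):
                raise ValueError(f"infeasible beta moments mean={m} se={self.se}")
            nu = m * (1 - m) / v - 1.0
            return float(rng.beta(m * nu, (1 - m) * nu))
        if self.kind == "gamma":
            if self.mean <= 0:
                raise ValueError("gamma mean must be > 0")
            shape = (self.mean / self.se) ** 2
            scale = self.se**2 / self.mean
            return float(rng.gamma(shape, scale))
        if self.kind == "lognormal_multiplier":
            # multiplier with mean `mean` and sd `se` applied to the base value
            cv2 = (self.se / self.mean) ** 2
            sigma2 = math.log1p(cv2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return float(rng.lognormal(mu, math.sqrt(sigma2)))
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class PSADraw:
    params: dict  # sampled parameter values by path
    delta_cost: float
    delta_qaly: float


def run_psa(
    base_params: ScenarioParams,
    distributions: dict,
    n_iter: int,
    seed: int,
    model_runner,
) -> list[PSADraw]:
    """Monte-Carlo parameter uncertainty: each draw runs the full model."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng([int(seed) % (2**31), 15485863])
    draws = []
    for _ in range(n_iter):
        sampled = {}
        trial = copy.deepcopy(base_params)
        for path, dist in distributions.items():
            if dist.kind == "lognormal_multiplier":
                value = get_param(base_params, path) * dist.sample(rng)
            else:
                value = dist.sample(rng)
            sampled[path] = value
            set_param(trial, path, value)
        res = model_runner(trial)
        draws.append(PSADraw(params=sampled, delta_cost=res.delta_cost, delta_qaly=res.delta_qaly))
    return draws


def ceac_curve(draws, wtp_grid) -> list[tuple[float, float]]:
    """Probability of positive net monetary benefit at each WTP threshold."""
    if not len(draws):
        raise ValueError("no PSA draws")
    dc = np.array([d.delta_cost for d in draws])
    de = np.array([d.delta_qaly for d in draws])
    return [(float(w), float(np.mean(w * de - dc > 0.0))) for w in wtp_grid]


def default_dsa_ranges(params: ScenarioParams, frac: float = 0.2) -> dict:
    """+-20% ranges around base for the influential parameters."""
    paths = [
        "config.utilities.pfs_durvalumab",
        "config.utilities.pfs",
        "config.utilities.pod",
        "config.drug_prices.durvalumab",
        "config.drug_prices.pembrolizumab",
        "config.drug_prices.osimertinib_monthly",
        "config.admin_cost_per_hour",
        "config.imaging_cost",
        "config.death_cost_nsclc",
        "config.monthly_bsc_cost",
        "tail_multipliers.durvalumab_os",
        "tail_multipliers.placebo_os",
    ]
    ranges = {}
    for path in paths:
        base = get_param(params, path)
        lo, hi = base * (1 - frac), base * (1 + frac)
        if "utilities" in path:
            hi = min(hi, 1.0)
        ranges[path] = (lo, hi)
    return ranges


def default_psa_distributions(params: ScenarioParams) -> dict:
    """HTA-convention defaults: beta utilities (SE 10% of mean), gamma costs
    (SE 20%), lognormal multipliers on extrapolation tail rates (SE 10%)."""
    dists = {}
    for path in ("config.utilities.pfs_durvalumab", "config.utilities.pfs", "config.utilities.pod"):
        m = get_param(params, path)
        dists[path] = Distribution("beta", m, 0.10 * m)
    cost_paths = [f"config.drug_prices.{k}" for k in params.config.drug_prices] + [
        "config.admin_cost_per_hour",
        "config.imaging_cost",
        "config.ihc_cost",
        "config.death_cost_nsclc",
        "config.death_cost_other",
        "config.monthly_bsc_cost",
    ]
    for path in cost_paths:
        m = get_param(params, path)
        if m > 0:
            dists[path] = Distribution("gamma", m, 0.20 * m)
    for key in params.tail_multipliers:
        dists[f"tail_multipliers.{key}"] = Distribution("lognormal_multiplier", 1.0, 0.10)
    return dists
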