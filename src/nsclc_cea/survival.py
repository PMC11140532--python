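"""Survival-curve reconstruction and the composite step + exponential-tail model.

The event-time distributions that drive every health-state transition in the
microsimulation are represented as *composite* survival functions: a
nonparametric (Kaplan-Meier) step function up to last follow-up, joined to an
exponential tail beyond it.  Published curves enter the pipeline as digitized
coordinates, are converted to pseudo individual-patient data (IPD), refit by
the product-limit estimator, and extrapolated with the exponential maximum
likelihood rate estimated on the tail window.

All times are in months; one model cycle equals one month (30 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "DigitizedCurve",
    "StepSurvival",
    "CompositeSurvival",
    "CurveValidationError",
    "ExtinctSurvivalError",
    "reconstruct_ipd",
    "km_fit",
    "fit_exponential_tail",
    "fit_composite",
    "exponential_survival",
    "monthly_transition_prob",
    "monthly_transition_probs",
    "median_survival",
]


class CurveValidationError(ValueError):
    """Raised when digitized curve coordinates violate survival-curve axioms."""


class ExtinctSurvivalError(ValueError):
    """Raised when a transition probability is requested past extinction (S=0)."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized Kaplan-Meier coordinates for one arm and endpoint.

    Parameters
    ----------
    times : months, strictly increasing, starting at 0
    survival : survival probabilities, nonincreasing, ``survival[0] == 1``
    numbers_at_risk : optional ``(time, count)`` pairs from the at-risk table
    last_followup : months; defaults to the last digitized time
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    numbers_at_risk: tuple[tuple[float, int], ...] | None = None
    last_followup: float | None = None

    def __init__(self, times, survival, numbers_at_risk=None, last_followup=None):
        times = tuple(float(t) for t in times)
        survival = tuple(float(s) for s in survival)
        if len(times) != len(survival) or not times:
            raise CurveValidationError("times and survival must be equal-length, nonempty")
        if times[0] != 0.0 or abs(survival[0] - 1.0) > 1e-9:
            raise CurveValidationError("curve must start at (time=0, survival=1)")
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise CurveValidationError(
                    f"times must be strictly increasing (offending point index {i}, t={times[i]})"
                )
            if survival[i] > survival[i - 1] + 1e-12:
                raise CurveValidationError(
                    f"survival must be nonincreasing (offending point index {i}, "
                    f"t={times[i]}, S={survival[i]} > {survival[i - 1]})"
                )
        for s in survival:
            if not 0.0 <= s <= 1.0:
                raise CurveValidationError(f"survival value {s} outside [0, 1]")
        if last_followup is None:
            last_followup = times[-1]
        if last_followup < times[-1]:
            raise CurveValidationError("last_followup must be >= the last digitized time")
        if numbers_at_risk is not None:
            numbers_at_risk = tuple((float(t), int(n)) for t, n in numbers_at_risk)
            for _, n in numbers_at_risk:
                if n < 0:
                    raise CurveValidationError("at-risk counts must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", survival)
        object.__setattr__(self, "numbers_at_risk", numbers_at_risk)
        object.__setattr__(self, "last_followup", float(last_followup))


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous, piecewise-constant survival function.

    ``breakpoints`` are the event times; the function equals 1 on
    ``[0, breakpoints[0])`` and ``values[i]`` on
    ``[breakpoints[i], breakpoints[i+1])``.
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]
    at_risk_per_interval: tuple[int, ...] | None = None

    def __post_init__(self):
        if len(self.breakpoints) != len(self.values):
            raise CurveValidationError("breakpoints and values must be equal length")
        for i in range(1, len(self.values)):
            if self.values[i] > self.values[i - 1] + 1e-12:
                raise CurveValidationError("step survival must be nonincreasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if len(self.breakpoints) == 0:
            return np.ones_like(t) if t.shape else 1.0
        idx = np.searchsorted(self.breakpoints, t, side="right")
        vals = np.concatenate(([1.0], np.asarray(self.values)))
        out = vals[idx]
        return out if t.shape else float(out)


@dataclass(frozen=True)
class CompositeSurvival:
    """Step body up to last follow-up ``t_f``, exponential tail beyond it.

    ``S(t) = body(t)`` for ``t <= t_f`` and
    ``S(t) = body(t_f) * exp(-tail_rate * (t - t_f))`` for ``t > t_f``.
    """

    body: StepSurvival
    t_f: float
    tail_rate: float

    def __post_init__(self):
        if self.tail_rate < 0:
            raise CurveValidationError("tail rate must be >= 0")
        if self.t_f < 0:
            raise CurveValidationError("t_f must be >= 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        body_val = np.asarray(self.body(t), dtype=float)
        anchor = float(self.body(self.t_f))
        tail_val = anchor * np.exp(-self.tail_rate * np.maximum(t - self.t_f, 0.0))
        out = np.where(t <= self.t_f, body_val, tail_val)
        return out if t.shape else float(out)

    def median(self) -> float:
        return median_survival(self)


def exponential_survival(rate: float) -> CompositeSurvival:
    """Pure exponential survival with hazard ``rate`` per month."""
    if rate < 0:
        raise CurveValidationError("rate must be >= 0")
    return CompositeSurvival(body=StepSurvival((), ()), t_f=0.0, tail_rate=rate)


def reconstruct_ipd(curve: DigitizedCurve, assumed_n: int) -> list[tuple[float, int]]:
    """Reconstruct pseudo individual-patient data from digitized coordinates.

    Returns ``(event_time, event_indicator)`` records whose product-limit
    estimate matches the input curve at every digitized time within
    ``1/assumed_n``.  When an at-risk table is available the number of
    censorings per interval is chosen to be consistent with it (a simplified
    digitized-curve reconstruction); otherwise no losses to follow-up are
    assumed before last follow-up, and all survivors are censored there.
    """
    if assumed_n < 1:
        raise ValueError("assumed_n must be >= 1")
    records: list[tuple[float, int]] = []
    if curve.numbers_at_risk:
        records = _reconstruct_with_at_risk(curve)
    else:
        # no losses to follow-up before t_f: the product-limit estimate equals
        # the empirical survival, so cumulative rounding keeps the running
        # event count within 0.5 of assumed_n * (1 - S(t)) at every time
        events_so_far = 0
        for t, s in zip(curve.times[1:], curve.survival[1:]):
            target = round(assumed_n * (1.0 - s))
            d = min(max(target - events_so_far, 0), assumed_n - events_so_far)
            records.extend([(t, 1)] * d)
            events_so_far += d
        records.extend([(curve.last_followup, 0)] * (assumed_n - events_so_far))
    return records


def _reconstruct_with_at_risk(curve: DigitizedCurve) -> list[tuple[float, int]]:
    # Interval-wise allocation: within each at-risk interval, events are set by
    # the survival drop and censorings by the deficit against the next at-risk
    # count, censorings spread uniformly over the interval.
    risk_times = [t for t, _ in curve.numbers_at_risk]
    risk_counts = [n for _, n in curve.numbers_at_risk]
    records: list[tuple[float, int]] = []
    s_fit = 1.0
    times = list(curve.times)
    surv = list(curve.survival)
    n_cur = risk_counts[0]
    for k in range(len(risk_times)):
        t_lo = risk_times[k]
        t_hi = risk_times[k + 1] if k + 1 < len(risk_times) else curve.last_followup
        pts = [(t, s) for t, s in zip(times, surv) if t_lo < t <= t_hi]
        d_interval = 0
        for t, s in pts:
            if n_cur == 0:
                break
            ratio = s / s_fit if s_fit > 0 else 1.0
            d = round(n_cur * (1.0 - ratio))
            d = min(max(d, 0), n_cur)
            records.extend([(t, 1)] * d)
            s_fit *= 1.0 - d / n_cur
            n_cur -= d
            d_interval += d
        if k + 1 < len(risk_times):
            c = n_cur - risk_counts[k + 1]
            c = min(max(c, 0), n_cur)
            if c:
                # censor uniformly within (t_lo, t_hi]
                cens_times = np.linspace(t_lo, t_hi, c + 2)[1:-1] if c > 1 else [(t_lo + t_hi) / 2]
                records.extend([(float(tc), 0) for tc in cens_times])
                n_cur -= c
    records.extend([(curve.last_followup, 0)] * n_cur)
    return records


def km_fit(ipd: Sequence[tuple[float, int]]) -> StepSurvival:
    """Product-limit (Kaplan-Meier) estimate of pseudo-IPD records."""
    if not len(ipd):
        raise ValueError("ipd must be nonempty")
    times = np.asarray([t for t, _ in ipd], dtype=float)
    events = np.asarray([e for _, e in ipd], dtype=int)
    if np.any(times < 0):
        raise ValueError("event times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    bp = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    mask = bp > 0
    table = kmf.event_table
    at_risk = table.loc[table.index > 0, "at_risk"].astype(int)
    return StepSurvival(
        breakpoints=tuple(bp[mask]),
        values=tuple(vals[mask]),
        at_risk_per_interval=tuple(int(at_risk.get(t, 0)) for t in bp[mask]),
    )


def fit_exponential_tail(
    ipd: Sequence[tuple[float, int]],
    t_f: float,
    fallback_body: StepSurvival | None = None,
) -> float:
    """Exponential MLE hazard on the tail window beyond ``t_f``.

    lambda = events after t_f / person-time at risk after t_f.  If no subject
    contributes person-time past ``t_f``, the hazard of the last interval of
    ``fallback_body`` is reused; failing that, 0 (a plateau is extrapolated
    flat rather than crashing).
    """
    if t_f <= 0:
        raise ValueError("t_f must be > 0")
    events = 0
    person_time = 0.0
    for t, e in ipd:
        if t > t_f:
            person_time += t - t_f
            events += int(e)
    if person_time > 0:
        return events / person_time
    return _last_interval_hazard(fallback_body)


def _last_interval_hazard(body: StepSurvival | None) -> float:
    if body is None or len(body.breakpoints) == 0:
        return 0.0
    bp = body.breakpoints
    vals = body.values
    s_hi = vals[-1]
    s_lo = vals[-2] if len(vals) > 1 else 1.0
    t_hi = bp[-1]
    t_lo = bp[-2] if len(bp) > 1 else 0.0
    if s_hi <= 0 or s_lo <= 0 or t_hi <= t_lo:
        return 0.0
    return math.log(s_lo / s_hi) / (t_hi - t_lo)


def fit_composite(
    curve: DigitizedCurve, assumed_n: int, t_f: float | None = None
) -> CompositeSurvival:
    """Full reconstruction pipeline: pseudo-IPD -> KM body -> exponential tail."""
    ipd = reconstruct_ipd(curve, assumed_n)
    body = km_fit(ipd)
    if t_f is None:
        t_f = curve.last_followup
    rate = fit_exponential_tail(ipd, t_f, fallback_body=body)
    return CompositeSurvival(body=body, t_f=float(t_f), tail_rate=rate)


def monthly_transition_prob(s: CompositeSurvival, cycle: int) -> float:
    """Probability of the event within cycle ``[cycle, cycle+1)`` given alive at ``cycle``."""
    s0 = float(s(float(cycle)))
    if s0 <= 0.0:
        raise ExtinctSurvivalError(f"survival is 0 at cycle {cycle}; query past extinction")
    s1 = float(s(float(cycle + 1)))
    return min(max(1.0 - s1 / s0, 0.0), 1.0)


def monthly_transition_probs(s: CompositeSurvival, horizon: int) -> np.ndarray:
    """Vector of monthly event probabilities for cycles 0..horizon-1.

    Cycles at which the curve is already extinct get probability 1 (the event
    must already have happened; the simulator never reaches them alive).
    """
    grid = s(np.arange(horizon + 1, dtype=float))
    grid = np.asarray(grid, dtype=float)
    p = np.ones(horizon)
    pos = grid[:-1] > 0
    p[pos] = 1.0 - grid[1:][pos] / grid[:-1][pos]
    return np.clip(p, 0.0, 1.0)


def median_survival(s: CompositeSurvival) -> float:
    """Smallest t with S(t) <= 0.5; ``inf`` if the curve never crosses 0.5."""
    body = s.body
    for t, v in zip(body.breakpoints, body.values):
        if t > s.t_f:
            break
        if v <= 0.5:
            return float(t)
    anchor = float(body(s.t_f))
    if anchor <= 0.5:  # crossing at a breakpoint beyond t_f is impossible: body frozen
        return float(s.t_f)
    if s.tail_rate <= 0:
        return math.inf
    return s.t_f + math.log(anchor / 0.5) / s.tail_rate
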