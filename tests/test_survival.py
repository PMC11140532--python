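"""Survival reconstruction, composite model, hazards and medians."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsclc_cea.survival import (
    CompositeSurvival,
    CurveValidationError,
    DigitizedCurve,
    ExtinctSurvivalError,
    StepSurvival,
    exponential_survival,
    fit_composite,
    fit_exponential_tail,
    km_fit,
    median_survival,
    monthly_transition_prob,
    monthly_transition_probs,
    reconstruct_ipd,
)


class TestDigitizedCurve:
    def test_rejects_non_monotone_survival(self):
        with pytest.raises(CurveValidationError, match="nonincreasing"):
            DigitizedCurve([0, 1, 2], [1.0, 0.5, 0.6])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(CurveValidationError, match="strictly increasing"):
            DigitizedCurve([0, 2, 2], [1.0, 0.8, 0.7])

    def test_must_start_at_origin(self):
        with pytest.raises(CurveValidationError):
            DigitizedCurve([1, 2], [1.0, 0.5])


class TestReconstructIPD:
    def test_two_subject_curve(self):
        curve = DigitizedCurve([0, 1], [1.0, 0.5])
        ipd = reconstruct_ipd(curve, assumed_n=2)
        assert sorted(ipd) == [(1.0, 0), (1.0, 1)]

    def test_flat_curve_has_no_events(self):
        curve = DigitizedCurve([0, 24], [1.0, 1.0])
        ipd = reconstruct_ipd(curve, assumed_n=7)
        assert all(e == 0 for _, e in ipd)
        assert all(t == 24 for t, _ in ipd)

    @pytest.mark.parametrize("n", [10, 100, 500])
    def test_round_trip_within_one_over_n(self, n):
        rho = 0.05
        times = np.arange(0.0, 36.5, 1.0)
        curve = DigitizedCurve(times, np.exp(-rho * times))
        step = km_fit(reconstruct_ipd(curve, assumed_n=n))
        for t, s in zip(curve.times, curve.survival):
            assert abs(float(step(t)) - s) <= 1.0 / n + 1e-12

    @given(
        drops=st.lists(st.floats(0.0, 0.2), min_size=3, max_size=12),
        n=st.integers(20, 300),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, drops, n):
        surv = [1.0]
        for d in drops:
            surv.append(max(surv[-1] * (1.0 - d), 0.0))
        times = list(range(len(surv)))
        curve = DigitizedCurve(times, surv)
        step = km_fit(reconstruct_ipd(curve, assumed_n=n))
        for t, s in zip(curve.times, curve.survival):
            assert abs(float(step(t)) - s) <= 1.0 / n + 1e-12

    def test_with_at_risk_table(self):
        # at-risk counts force interior censoring; KM should still track
        times = [0, 6, 12, 18, 24]
        surv = [1.0, 0.8, 0.65, 0.55, 0.5]
        curve = DigitizedCurve(
            times, surv, numbers_at_risk=[(0, 100), (12, 55), (24, 40)]
        )
        ipd = reconstruct_ipd(curve, assumed_n=100)
        step = km_fit(ipd)
        for t, s in zip(times, surv):
            assert abs(float(step(t)) - s) <= 0.05


class TestKMFit:
    def test_hand_product_limit(self):
        step = km_fit([(2, 1), (4, 1), (4, 1), (6, 0), (8, 1)])
        assert float(step(2)) == pytest.approx(0.8)
        assert float(step(4)) == pytest.approx(0.4)
        assert float(step(8)) == pytest.approx(0.0)

    def test_all_censored_is_flat(self):
        step = km_fit([(3, 0), (5, 0), (9, 0)])
        assert float(step(100.0)) == 1.0

    def test_single_subject(self):
        step = km_fit([(5, 1)])
        assert float(step(4.99)) == 1.0
        assert float(step(5)) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_fit([(-1, 1)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_fit([])


class TestExponentialTail:
    def test_events_over_person_time(self):
        # two subjects at risk past t_f=12, 3 and 5 extra months, both events
        assert fit_exponential_tail([(15, 1), (17, 1)], 12) == pytest.approx(0.25)

    def test_no_events_is_plateau(self):
        assert fit_exponential_tail([(20, 0), (30, 0)], 12) == 0.0

    def test_recovers_exponential_rate(self):
        rng = np.random.default_rng(7)
        lam = 0.05
        times = rng.exponential(1.0 / lam, size=5000)
        t_f = float(np.median(times))
        ipd = [(float(t), 1) for t in times]
        lam_hat = fit_exponential_tail(ipd, t_f)
        assert abs(lam_hat - lam) / lam < 0.10

    def test_fallback_uses_last_body_interval(self):
        # no person-time past t_f: reuse last KM interval hazard
        ipd = [(1, 1), (2, 1), (2, 0), (2, 0)]
        body = km_fit(ipd)
        lam = fit_exponential_tail(ipd, 2.0, fallback_body=body)
        # last interval (1, 2]: S drops 0.75 -> 0.5
        assert lam == pytest.approx(math.log(0.75 / 0.5), rel=1e-9)


class TestCompositeSurvival:
    def test_monthly_prob_constant_curve(self):
        flat = CompositeSurvival(StepSurvival((), ()), t_f=0.0, tail_rate=0.0)
        assert monthly_transition_prob(flat, 5) == 0.0

    def test_monthly_prob_exponential_closed_form(self):
        s = exponential_survival(0.1)
        expected = 1.0 - math.exp(-0.1)
        for cycle in (0, 7, 60):
            assert monthly_transition_prob(s, cycle) == pytest.approx(expected)

    def test_monthly_probs_telescope_back_to_survival(self, us_bundle):
        s = us_bundle.arm_models["placebo"].os_curve
        p = monthly_transition_probs(s, 120)
        recon = np.cumprod(1.0 - p)
        grid = np.arange(1, 121, dtype=float)
        np.testing.assert_allclose(recon, np.asarray(s(grid)), rtol=1e-10)

    def test_extinct_query_raises(self):
        dead = CompositeSurvival(StepSurvival((1.0,), (0.0,)), t_f=2.0, tail_rate=0.0)
        with pytest.raises(ExtinctSurvivalError):
            monthly_transition_prob(dead, 3)

    def test_continuity_at_followup_boundary(self, us_bundle):
        for model in us_bundle.arm_models.values():
            for s in (model.pfs_curve, model.os_curve):
                assert float(s(s.t_f)) == pytest.approx(float(s(s.t_f + 1e-9)), rel=1e-6)

    def test_globally_nonincreasing(self, us_bundle):
        grid = np.linspace(0, 200, 2000)
        for model in us_bundle.arm_models.values():
            for s in (model.pfs_curve, model.os_curve):
                vals = np.asarray(s(grid))
                assert vals.max() <= 1.0 + 1e-12
                assert np.all(np.diff(vals) <= 1e-12)


class TestMedianSurvival:
    def test_exponential_closed_form(self):
        assert median_survival(exponential_survival(math.log(2))) == pytest.approx(1.0)

    def test_plateau_above_half_never_crosses(self):
        body = StepSurvival((1.0, 2.0), (0.8, 0.55))
        s = CompositeSurvival(body, t_f=2.0, tail_rate=0.0)
        assert median_survival(s) == math.inf

    def test_composite_median_converges_on_exponential_data(self):
        rng = np.random.default_rng(11)
        lam = 0.04
        n = 5000
        times = rng.exponential(1.0 / lam, size=n)
        t_f = float(np.quantile(times, 0.5))
        ipd = [(min(float(t), t_f * 2), int(t <= t_f * 2)) for t in times]
        body = km_fit(ipd)
        comp = CompositeSurvival(
            body, t_f=t_f, tail_rate=fit_exponential_tail(ipd, t_f, fallback_body=body)
        )
        assert abs(median_survival(comp) - math.log(2) / lam) / (math.log(2) / lam) < 0.05

    def test_fit_composite_median_in_tail_region(self):
        # median beyond t_f must come from the closed-form tail
        curve = DigitizedCurve(np.arange(0, 31.0), np.exp(-0.02 * np.arange(0, 31.0)))
        comp = fit_composite(curve, assumed_n=400, t_f=20.0)
        assert median_survival(comp) == pytest.approx(math.log(2) / 0.02, rel=0.06)
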