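"""Microsimulation mechanics: state order, marginal tracking, determinism."""

import math

import numpy as np
import pytest

from nsclc_cea.outcomes import km_median
from nsclc_cea.patients import generate_patients
from nsclc_cea.simulate import DEATH, PFS, POD1, POD2, ArmModel, simulate_arm, simulate_cohort
from nsclc_cea.survival import CompositeSurvival, StepSurvival, exponential_survival
from nsclc_cea.synthetic import LINE2_MEDIANS, make_country_config

LN2 = math.log(2.0)


def _arm_models(pfs_rate=0.03, os_rate=0.015, line2_rate=LN2 / 8.8, line3_rate=LN2 / 10.5):
    line2 = {name: exponential_survival(line2_rate) for name in LINE2_MEDIANS}
    model = ArmModel(
        pfs_curve=exponential_survival(pfs_rate),
        os_curve=exponential_survival(os_rate),
        line2_ttp_curves=line2,
        line3_os_curve=exponential_survival(line3_rate),
    )
    return {"durvalumab": model, "placebo": model}


@pytest.fixture(scope="module")
def cohort():
    return generate_patients(400, seed=3)


class TestDegenerateHazards:
    def test_zero_hazards_keep_everyone_progression_free(self, cohort, us_config):
        models = _arm_models(pfs_rate=0.0, os_rate=0.0, line2_rate=0.0, line3_rate=0.0)
        traces = simulate_arm(cohort, "durvalumab", models, us_config, 120, seed=1)
        assert all(tr.death_month is None and tr.progression1_month is None for tr in traces)
        assert all((tr.states == PFS).all() for tr in traces)

    def test_certain_death_in_first_cycle(self, cohort, us_config):
        # OS curve dropping to 0 within the first month kills everyone at month 1
        dead_curve = CompositeSurvival(StepSurvival((1.0,), (0.0,)), t_f=1.0, tail_rate=0.0)
        models = _arm_models()
        for arm in models:
            models[arm] = ArmModel(
                pfs_curve=models[arm].pfs_curve,
                os_curve=dead_curve,
                line2_ttp_curves=models[arm].line2_ttp_curves,
                line3_os_curve=models[arm].line3_os_curve,
            )
        traces = simulate_arm(cohort, "placebo", models, us_config, 120, seed=1)
        assert all(tr.death_month == 1 for tr in traces)


class TestStateOrder:
    def test_no_backward_moves_and_death_absorbing(self, us_base_traces):
        _, traces = us_base_traces
        for arm in traces:
            for tr in traces[arm]:
                s = tr.states.astype(int)
                assert np.all(np.diff(s) >= 0), "state order regressed"
                dead = np.where(s == DEATH)[0]
                if len(dead):
                    assert (s[dead[0]:] == DEATH).all()

    def test_event_month_ordering(self, us_base_traces):
        _, traces = us_base_traces
        for arm in traces:
            for tr in traces[arm]:
                months = [tr.progression1_month, tr.progression2_month, tr.death_month]
                present = [m for m in months if m is not None]
                assert present == sorted(present)
                if tr.progression2_month is not None:
                    assert tr.progression1_month is not None

    def test_death_cause_follows_progression_status(self, us_base_traces):
        _, traces = us_base_traces
        for arm in traces:
            for tr in traces[arm]:
                if tr.death_month is None:
                    assert tr.death_cause is None
                elif tr.progression1_month is not None and tr.progression1_month < tr.death_month:
                    assert tr.death_cause == "nsclc"
                else:
                    assert tr.death_cause == "other"


class TestMarginalTracking:
    def test_progression_free_survival_tracks_configured_curve(self, us_config):
        # median of simulated PFS-exit times converges to the curve median
        patients = generate_patients(20_000, seed=5)
        models = _arm_models(pfs_rate=LN2 / 20.0, os_rate=LN2 / 40.0)
        traces = simulate_arm(patients, "placebo", models, us_config, 120, seed=5)
        times = [tr.months_in_pfs for tr in traces]
        events = [1 if t < 120 else 0 for t in times]
        assert km_median(times, events) == pytest.approx(20.0, abs=0.6)

    def test_overall_survival_tracks_configured_curve(self, us_config):
        patients = generate_patients(20_000, seed=6)
        models = _arm_models(pfs_rate=LN2 / 20.0, os_rate=LN2 / 40.0)
        traces = simulate_arm(patients, "placebo", models, us_config, 120, seed=6)
        times = [tr.months_survived for tr in traces]
        events = [1 if tr.death_month is not None else 0 for tr in traces]
        assert km_median(times, events) == pytest.approx(40.0, abs=1.0)

    def test_progression_probability_never_needs_flooring(self):
        # for parametric curves with PFS hazard above OS hazard everywhere the
        # residual progression probability needs no flooring at all
        from nsclc_cea.survival import monthly_transition_probs

        pfs = exponential_survival(LN2 / 19.9)
        os_ = exponential_survival(LN2 / 39.3)
        p_pfs = monthly_transition_probs(pfs, 120)
        p_os = monthly_transition_probs(os_, 120)
        assert np.all(p_pfs - p_os >= -1e-9)

    def test_reconstructed_curves_clamp_only_at_rounding_granularity(self, us_bundle):
        # step bodies rebuilt from integer patient counts can locally invert
        # the monthly hazard ordering, but never by more than ~2 subjects
        from nsclc_cea.survival import monthly_transition_probs

        for arm, n in (("durvalumab", 476), ("placebo", 237)):
            model = us_bundle.arm_models[arm]
            p_pfs = monthly_transition_probs(model.pfs_curve, 120)
            p_os = monthly_transition_probs(model.os_curve, 120)
            assert np.all(p_pfs - p_os >= -2.5 / n)


class TestDirectTransitions:
    def test_rare_direct_pfs_to_pod2(self, cohort, us_config):
        # a fast second-line hazard makes same-cycle double progressions
        # possible but uncommon
        models = _arm_models(pfs_rate=0.08, os_rate=0.01, line2_rate=LN2 / 4.9)
        traces = simulate_arm(cohort, "placebo", models, us_config, 120, seed=2)
        direct = [
            tr
            for tr in traces
            if tr.progression2_month is not None
            and tr.progression2_month == tr.progression1_month
        ]
        assert 0 < len(direct) < 0.2 * len(traces)


class TestDeterminism:
    def test_fixed_seed_bit_identical(self, cohort, us_config):
        models = _arm_models()
        a = simulate_cohort(cohort, models, us_config, 60, seed=11)
        b = simulate_cohort(cohort, models, us_config, 60, seed=11)
        for arm in a:
            for ta, tb in zip(a[arm], b[arm]):
                assert ta.death_month == tb.death_month
                assert ta.progression1_month == tb.progression1_month
                assert ta.progression2_month == tb.progression2_month
                assert (ta.states == tb.states).all()

    def test_cohort_extension_preserves_early_patients(self, us_config):
        # patient i's uniforms do not depend on cohort size
        small = generate_patients(30, seed=4)
        large = generate_patients(60, seed=4)
        models = _arm_models(line2_rate=0.0, line3_rate=0.0)  # no cohort coupling
        a = simulate_arm(small, "placebo", models, us_config, 60, seed=4)
        b = simulate_arm(large, "placebo", models, us_config, 60, seed=4)
        for ta, tb in zip(a, b[:30]):
            assert ta.death_month == tb.death_month
            assert ta.progression1_month == tb.progression1_month


class TestValidation:
    def test_missing_regimen_curve_fails_before_simulation(self, cohort, us_config):
        models = _arm_models()
        incomplete = {name: c for name, c in models["placebo"].line2_ttp_curves.items()
                      if name != "osimertinib"}
        for arm in models:
            models[arm] = ArmModel(
                pfs_curve=models[arm].pfs_curve,
                os_curve=models[arm].os_curve,
                line2_ttp_curves=incomplete,
                line3_os_curve=models[arm].line3_os_curve,
            )
        with pytest.raises(ValueError, match="osimertinib"):
            simulate_arm(cohort, "placebo", models, us_config, 120, seed=1)

    def test_bad_horizon_rejected(self, cohort, us_config):
        with pytest.raises(ValueError):
            simulate_arm(cohort, "placebo", _arm_models(), us_config, 0, seed=1)
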