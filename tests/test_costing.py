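"""Dosing rules, discounting, currency, regimen/AE costing, access pricing."""

import math

import pytest

from nsclc_cea.costing import (
    AE_INCIDENCE,
    REGIMENS,
    AccessProgram,
    ConfigurationError,
    DrugComponent,
    access_program_price_per_mg,
    adverse_event_cost,
    convert_currency,
    cost_trace,
    creatinine_clearance,
    discount_value,
    dose_amount,
    regimen_cost,
)
from nsclc_cea.patients import PatientProfile


class TestDoseAmount:
    def test_weight_based(self):
        comp = REGIMENS["durvalumab"].components[0]
        p = PatientProfile("male", 70.0, 1.9, 1.0, 64, "nonsquamous", "tps_ge1", False, False)
        assert dose_amount(comp, p) == pytest.approx(700.0)

    def test_bsa_based(self, female_base_case):
        comp = DrugComponent("pemetrexed", "per_bsa", 500.0, 0.17, 21.0, 31)
        assert dose_amount(comp, female_base_case) == pytest.approx(910.0)

    def test_calvert_with_cockcroft_gault(self, female_base_case):
        # AUC 5 x (CrCl + 25); female base case CrCl = 72.43 mL/min
        comp = DrugComponent("carboplatin", "carboplatin_auc", 5.0, 0.5, 21.0, 4)
        assert creatinine_clearance(female_base_case) == pytest.approx(72.43, abs=0.01)
        assert dose_amount(comp, female_base_case) == pytest.approx(487.2, abs=0.5)

    def test_clearance_capped(self):
        young = PatientProfile("male", 120.0, 2.4, 0.5, 25, "squamous", "unknown", False, False)
        assert creatinine_clearance(young) == 125.0

    def test_missing_creatinine_rejected(self):
        p = PatientProfile("male", 80.0, 2.0, 0.0, 64, "squamous", "unknown", False, False)
        comp = DrugComponent("carboplatin", "carboplatin_auc", 5.0, 0.5, 21.0, 4)
        with pytest.raises(ConfigurationError, match="creatinine"):
            dose_amount(comp, p)


class TestDiscounting:
    def test_month_zero_is_undiscounted(self):
        assert discount_value(100.0, 0) == 100.0

    def test_one_year_factor(self):
        assert discount_value(1.0, 12, 0.03) == pytest.approx(1 / 1.03)

    def test_strictly_decreasing(self):
        factors = [discount_value(1.0, m, 0.03) for m in range(0, 60, 6)]
        assert all(a > b for a, b in zip(factors, factors[1:]))


class TestCurrency:
    @pytest.mark.parametrize("native, rate", [(253.0, 2.53), (134.0, 1.34), (100.0, 1.0)])
    def test_native_per_usd_rates(self, native, rate, us_config):
        cfg = us_config.__class__(**{**us_config.__dict__, "currency_to_usd": rate})
        assert convert_currency(native, cfg) == pytest.approx(native / rate)

    def test_nonpositive_rate_rejected(self, us_config):
        with pytest.raises(ConfigurationError):
            us_config.__class__(**{**us_config.__dict__, "currency_to_usd": 0.0})


class TestRegimenCost:
    def test_zero_months_costs_nothing(self, female_base_case, us_config):
        assert regimen_cost(REGIMENS["durvalumab"], female_base_case, 0.0, us_config) == (0, 0)

    def test_single_durvalumab_administration(self, us_config):
        p = PatientProfile("male", 70.0, 1.9, 1.0, 64, "nonsquamous", "tps_ge1", False, False)
        acq, admin = regimen_cost(
            REGIMENS["durvalumab"], p, 0.5, us_config, discounting=False
        )
        assert acq == pytest.approx(700 * 7.71)
        assert admin == pytest.approx(205.43)

    def test_oral_monthly_pricing(self, female_base_case, us_config):
        acq, admin = regimen_cost(
            REGIMENS["osimertinib"], female_base_case, 3, us_config, discounting=False
        )
        assert acq == pytest.approx(3 * 17079.18)
        assert admin == 0.0

    def test_max_cycles_cap(self, female_base_case, us_config):
        # durvalumab q2w caps at 24 administrations however long the PFS
        a24, _ = regimen_cost(REGIMENS["durvalumab"], female_base_case, 40, us_config,
                              discounting=False)
        a120, _ = regimen_cost(REGIMENS["durvalumab"], female_base_case, 120, us_config,
                               discounting=False)
        assert a24 == pytest.approx(24 * 775 * 7.71)
        assert a120 == a24

    def test_discounting_reduces_cost(self, female_base_case, us_config):
        undisc, _ = regimen_cost(REGIMENS["durvalumab"], female_base_case, 12, us_config,
                                 discounting=False)
        disc, _ = regimen_cost(REGIMENS["durvalumab"], female_base_case, 12, us_config)
        assert 0 < disc < undisc

    def test_unknown_drug_rejected(self, female_base_case, us_config):
        from nsclc_cea.costing import Regimen

        reg = Regimen("x", (DrugComponent("nonexistent", "flat", 1.0, 0.0, 30.0, 1),), "docetaxel")
        with pytest.raises(ConfigurationError, match="nonexistent"):
            regimen_cost(reg, female_base_case, 1.0, us_config)


class TestAdverseEventCost:
    def test_durvalumab_expected_cost(self, us_config):
        # dot product of trial grade-3/4 incidences and US unit costs
        expected = (
            0.002 * 16185 + 0.015 * 6018 + 0.044 * 9941
            + 0.034 * 9941 + 0.006 * 3265 + 0.029 * 4353
        )
        assert adverse_event_cost("durvalumab_arm", us_config) == pytest.approx(expected)
        assert expected == pytest.approx(1044, abs=1)

    def test_zero_incidence_costs_nothing(self, us_config):
        table = {"zero": {t: 0.0 for t in AE_INCIDENCE["durvalumab_arm"]}}
        assert adverse_event_cost("zero", us_config, incidence_table=table) == 0.0

    def test_linear_in_unit_costs(self, us_config):
        doubled = us_config.__class__(
            **{**us_config.__dict__, "ae_unit_costs": {k: 2 * v for k, v in us_config.ae_unit_costs.items()}}
        )
        assert adverse_event_cost("docetaxel", doubled) == pytest.approx(
            2 * adverse_event_cost("docetaxel", us_config)
        )

    def test_missing_unit_cost_rejected(self, us_config):
        stripped = us_config.__class__(
            **{**us_config.__dict__, "ae_unit_costs": {"fatigue": 1.0}}
        )
        with pytest.raises(ConfigurationError, match="unit cost"):
            adverse_event_cost("durvalumab_arm", stripped)


class TestAccessProgram:
    def test_published_discount_fraction(self):
        program = AccessProgram(discount_fraction=0.337)
        assert access_program_price_per_mg(6.38, program) == pytest.approx(4.23, abs=0.005)

    def test_zero_discount_is_identity(self):
        program = AccessProgram(discount_fraction=0.0)
        assert access_program_price_per_mg(9.99, program) == 9.99

    def test_buy_one_get_two_free_single_vial(self):
        # requirement = an exact number of triplets -> pay a third of the value
        program = AccessProgram(vial_sizes_mg=(500.0,))
        assert access_program_price_per_mg(9.0, program, monthly_mg=1500.0) == pytest.approx(3.0)

    def test_uncoverable_requirement_rejected(self):
        program = AccessProgram(vial_sizes_mg=(500.0,))
        with pytest.raises(ConfigurationError):
            access_program_price_per_mg(9.0, program, monthly_mg=100.0)


class TestCostTrace:
    def test_components_nonnegative_and_decompose(self, us_base_traces, us_config):
        patients, traces = us_base_traces
        for arm in traces:
            for tr, p in list(zip(traces[arm], patients))[:200]:
                comps = cost_trace(tr, p, us_config)
                assert all(v >= 0 for v in comps.values())

    def test_gated_patient_accrues_no_durvalumab_cost(self, us_base_traces, us_config):
        patients, traces = us_base_traces
        # a durvalumab-arm trace rerouted to the placebo pathway costs no durvalumab
        tr = traces["durvalumab"][0]
        tr_gated = type(tr)(**{**tr.__dict__, "effective_arm": "placebo"})
        comps = cost_trace(tr_gated, patients[0], us_config)
        assert comps["pf_drug"] == pytest.approx(us_config.radiotherapy_cost)
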