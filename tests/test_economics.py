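"""Cost/QALY accrual, adherence mixing and incremental comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renalcea.economics import (AdherenceScenario, CostInputs, GroupTotals,
                                InterventionCostInputs, ProductivityInputs,
                                UtilityInputs, accrue, blended_wage,
                                dialysis_state_utility, icer,
                                intervention_cost_per_patient, mix_scenarios)
from renalcea.markov import (DEATH, FG1, DialysisMortality, OccupancyTrace,
                             RetransplantParams, build_transition_schedule,
                             run_trace)
from renalcea.survival import AnnualProbabilityVector


def undiscounted():
    return (CostInputs(discount_rate_costs=0.0),
            UtilityInputs(discount_rate_effects=0.0))


def trace_from(dwfg, gf, start_age=50.0):
    dwfg = AnnualProbabilityVector("dwfg", 1, np.asarray(dwfg, float))
    gf = AnnualProbabilityVector("graft_failure", 1, np.asarray(gf, float))
    zero_dial = DialysisMortality(bands={"50-54": 0.0, "55-59": 0.0,
                                         "60-64": 0.0, "65-69": 0.0,
                                         "70-74": 0.0, "75-79": 0.0,
                                         "80-84": 0.0, "85+": 0.0})
    retx = RetransplantParams(base_probability=0.0, primary_non_function=0.0)
    sched = build_transition_schedule(dwfg, gf, zero_dial, retx,
                                      start_age, len(dwfg.values))
    return run_trace(sched, cohort_size=1000.0)


class TestSimpleAggregates:
    def test_dialysis_utility_blend(self):
        assert dialysis_state_utility(UtilityInputs()) == pytest.approx(0.5628)
        assert dialysis_state_utility(
            UtilityInputs(hd_share=1.0)) == pytest.approx(0.56)
        assert dialysis_state_utility(
            UtilityInputs(hd_share=0.0)) == pytest.approx(0.58)

    def test_blended_wage(self):
        expected = 0.563 * 37.90 + (1 - 0.563) * 31.60
        assert blended_wage(ProductivityInputs()) == pytest.approx(expected)
        assert blended_wage(
            ProductivityInputs(male_share=1.0)) == pytest.approx(37.90)

    def test_equal_wages_ignore_share(self):
        p = ProductivityInputs(male_wage=33.0, female_wage=33.0,
                               male_share=0.2)
        assert blended_wage(p) == pytest.approx(33.0)

    def test_intervention_cost_per_patient(self):
        assert intervention_cost_per_patient(
            InterventionCostInputs()) == pytest.approx(514.64)
        assert intervention_cost_per_patient(
            InterventionCostInputs(n_visits=0)) == 0.0
        assert intervention_cost_per_patient(InterventionCostInputs(
            n_visits=1, fee_per_visit=60.0, km_to_dietician=0.0,
            parking=0.0)) == pytest.approx(60.0)


class TestAccrue:
    def test_single_state_single_cycle(self):
        costs, utilities = undiscounted()
        trace = trace_from([0.0], [0.0])
        totals = accrue(trace, costs, utilities, ProductivityInputs(),
                        "dash", 1, 50.0)
        assert totals.total_qalys == pytest.approx(810.0)
        assert totals.cost_by_category["transplant_upkeep"] == \
            pytest.approx(10_820_000.0)
        assert totals.cost_by_category["diet"] == 0.0  # group 1 pays nothing

    def test_mid_cycle_discounting(self):
        costs = CostInputs(discount_rate_costs=0.04)
        utilities = UtilityInputs(discount_rate_effects=0.0)
        trace = trace_from([0.0, 0.0], [0.0, 0.0])
        totals = accrue(trace, costs, utilities, ProductivityInputs(),
                        "dash", 1, 50.0)
        per_cycle = 1000.0 * 10820.0
        expected = per_cycle * (1.04 ** -0.5 + 1.04 ** -1.5)
        assert totals.cost_by_category["transplant_upkeep"] == \
            pytest.approx(expected)
        # sanity: 100 EUR accrued in cycle 1 at 4% discounts to ~94.29
        assert 100.0 * 1.04 ** -1.5 == pytest.approx(94.2867, abs=1e-4)

    def test_start_of_cycle_discounting_option(self):
        costs = CostInputs(discount_rate_costs=0.04)
        utilities = UtilityInputs(discount_rate_effects=0.0)
        trace = trace_from([0.0], [0.0])
        totals = accrue(trace, costs, utilities, ProductivityInputs(),
                        "dash", 1, 50.0, mid_cycle_discount=False)
        assert totals.cost_by_category["transplant_upkeep"] == \
            pytest.approx(1000.0 * 10820.0)

    def test_graft_failure_event_and_friction_cost(self):
        costs, utilities = undiscounted()
        prod = ProductivityInputs()
        # 1% graft failure in one cycle: exactly 10 of 1000 move FG1 -> GF1
        trace = trace_from([0.0], [0.01])
        totals = accrue(trace, costs, utilities, prod, "dash", 1, 50.0)
        assert totals.cost_by_category["graft_failure_events"] == \
            pytest.approx(10 * 2397.0)
        wage = blended_wage(prod)
        expected_friction = 10 * (0.57 - 0.32) * 85.0 * 8.0 * wage
        assert totals.cost_by_category["productivity"] == \
            pytest.approx(expected_friction)
        assert expected_friction == pytest.approx(59749.9, abs=1.0)

    def test_friction_antisymmetry_and_hospital_loss(self):
        # a forced GF1 -> FG2 return must repay the FG -> GF friction loss;
        # only the re-transplant hospital stay remains
        costs, utilities = undiscounted()
        prod = ProductivityInputs()
        occupancy = np.array([[10.0, 0, 0, 0, 0],
                              [0, 10.0, 0, 0, 0],
                              [0, 0, 10.0, 0, 0]])
        counts = np.zeros((2, 5, 5))
        counts[0, 0, 1] = 10.0  # FG1 -> GF1
        counts[1, 1, 2] = 10.0  # GF1 -> FG2
        trace = OccupancyTrace(10.0, occupancy, counts)
        totals = accrue(trace, costs, utilities, prod, "dash", 1, 50.0)
        wage = blended_wage(prod)
        hospital = 10 * 0.57 * 10.58 * 8.0 * wage
        assert totals.cost_by_category["productivity"] == \
            pytest.approx(hospital)
        assert totals.cost_by_category["transplantation_events"] == \
            pytest.approx(10 * 59949.0)

    def test_death_mass_accrues_nothing(self):
        costs, utilities = undiscounted()
        occupancy = np.array([[500.0, 0, 0, 0, 500.0],
                              [500.0, 0, 0, 0, 500.0]])
        trace = OccupancyTrace(1000.0, occupancy, np.zeros((1, 5, 5)))
        totals = accrue(trace, costs, utilities, ProductivityInputs(),
                        "dash", 1, 50.0)
        assert totals.total_qalys == pytest.approx(500.0 * 0.81)
        assert totals.cost_by_category["transplant_upkeep"] == \
            pytest.approx(500.0 * 10820.0)

    def test_diet_cost_only_in_functioning_graft_for_groups_2_3(self):
        costs, utilities = undiscounted()
        trace = trace_from([0.0], [0.0])
        g3 = accrue(trace, costs, utilities, ProductivityInputs(),
                    "dash", 3, 50.0)
        assert g3.cost_by_category["diet"] == pytest.approx(1000.0 * 365.0)
        g2 = accrue(trace, costs, utilities, ProductivityInputs(),
                    "potassium", 2, 50.0)
        assert g2.cost_by_category["diet"] == pytest.approx(1000.0 * 84.74)

    def test_discounting_monotone_in_rate(self):
        utilities = UtilityInputs(discount_rate_effects=0.0)
        trace = trace_from([0.01] * 10, [0.02] * 10)
        totals = [accrue(trace, CostInputs(discount_rate_costs=r), utilities,
                         ProductivityInputs(), "dash", 1, 50.0).total_cost
                  for r in (0.0, 0.02, 0.04, 0.08)]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_categories_sum_to_total(self):
        costs, utilities = undiscounted()
        trace = trace_from([0.01] * 20, [0.03] * 20)
        totals = accrue(trace, costs, utilities, ProductivityInputs(),
                        "dash", 2, 53.0)
        assert sum(totals.cost_by_category.values()) == \
            pytest.approx(totals.total_cost, rel=1e-9)


def group_totals(group, cost, qalys):
    return GroupTotals(diet="dash", group=group, total_cost=cost,
                       cost_by_category={"transplant_upkeep": cost},
                       total_qalys=qalys)


class TestMixing:
    G = (group_totals(1, 300e6, 9000.0), group_totals(2, 250e6, 11000.0),
         group_totals(3, 240e6, 12000.0))

    def test_identity_weights(self):
        cost, q = mix_scenarios(self.G, AdherenceScenario.no_intervention())
        assert cost == pytest.approx(300e6)
        assert q == pytest.approx(9000.0)

    @given(st.floats(0.0, 1.0))
    def test_incrementals_affine_in_group1_share(self, p):
        base = mix_scenarios(self.G, AdherenceScenario.no_intervention())
        full = mix_scenarios(self.G, AdherenceScenario.from_group1_share(0.0))
        at_p = mix_scenarios(self.G, AdherenceScenario.from_group1_share(p))
        assert at_p[1] - base[1] == pytest.approx(
            (1.0 - p) * (full[1] - base[1]), abs=1e-6)
        assert at_p[0] - base[0] == pytest.approx(
            (1.0 - p) * (full[0] - base[0]), abs=1e-3)

    def test_symmetric_groups_split_invariant(self):
        g = (self.G[0], group_totals(2, 250e6, 11000.0),
             group_totals(3, 250e6, 11000.0))
        a = mix_scenarios(g, AdherenceScenario(0.2, 0.5, 0.3))
        b = mix_scenarios(g, AdherenceScenario(0.2, 0.3, 0.5))
        assert a == pytest.approx(b)

    def test_intervention_cost_added_undiscounted(self):
        with_cost = mix_scenarios(self.G,
                                  AdherenceScenario.from_group1_share(0.0),
                                  intervention_cost_total=514640.0)
        without = mix_scenarios(self.G,
                                AdherenceScenario.from_group1_share(0.0))
        assert with_cost[0] - without[0] == pytest.approx(514640.0)
        assert with_cost[1] == without[1]

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AdherenceScenario(0.5, 0.3, 0.3)
        with pytest.raises(ValueError, match="non-negative"):
            AdherenceScenario(1.2, -0.1, -0.1)


class TestICER:
    def test_dominant(self):
        res = icer(-27_934_786.0, 1880.0)
        assert res.reported == "Dominant"

    def test_dominated(self):
        assert icer(100.0, -2.0).reported == "Dominated"

    def test_ratio_truncated_toward_zero(self):
        assert icer(168_552.0, 580.0).reported == "290"
        assert icer(341_846.0, 290.0).reported == "1178"

    def test_zero_qalys_undefined(self):
        assert icer(100.0, 0.0).reported == "undefined"

    @given(st.floats(-1e8, 1e8), st.floats(-1e4, 1e4))
    def test_classification_is_exhaustive(self, dc, dq):
        res = icer(dc, dq)
        if dq == 0:
            assert res.label == "undefined"
        elif dc < 0 and dq > 0:
            assert res.label == "Dominant"
        elif dc > 0 and dq < 0:
            assert res.label == "Dominated"
        else:
            assert res.icer_value == pytest.approx(dc / dq, nan_ok=True)
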