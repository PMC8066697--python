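"""Cost and QALY accounting over a Markov trace.

State accruals (upkeep costs, diet costs, utilities) use the mid-cycle
correction — the trapezoidal mean of successive occupancy rows — while
event accruals (graft failure, transplantation, death, friction-method
productivity losses) use the expected transition counts.  Everything
accrued in cycle t is discounted at t + 0.5, reflecting events happening
mid-year; costs and effects carry separate discount rates (4% and 1.5% in
the Dutch guideline defaults).  Group-level totals are then mixed across
adherence groups and compared incrementally (ICER or dominance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markov import DEATH, FG1, FG2, GF1, GF2, OccupancyTrace

COST_CATEGORIES = (
    "transplant_upkeep", "dialysis_upkeep", "diet",
    "graft_failure_events", "transplantation_events", "death_events",
    "productivity",
)


@dataclass
class CostInputs:
    """Annual state costs, one-off event costs (2017 euros) and the cost
    discount rate; diet costs are per diet and adherence group."""

    dialysis_upkeep: float = 87855.0
    transplant_upkeep: float = 10820.0
    transplantation_event: float = 59949.0
    death_event: float = 1165.0
    graft_failure_event: float = 2397.0
    diet_annual: dict = field(default_factory=lambda: {
        "dash": {1: 0.0, 2: 182.50, 3: 365.0},
        "potassium": {1: 0.0, 2: 84.74, 3: 169.47},
    })
    discount_rate_costs: float = 0.04

    def __post_init__(self) -> None:
        for name in ("dialysis_upkeep", "transplant_upkeep",
                     "transplantation_event", "death_event",
                     "graft_failure_event"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for diet, by_group in self.diet_annual.items():
            if by_group.get(1, 0.0) != 0.0:
                raise ValueError(f"{diet}: group-1 diet cost must be 0")
            if any(v < 0 for v in by_group.values()):
                raise ValueError(f"{diet}: diet costs must be non-negative")


@dataclass
class InterventionCostInputs:
    """One-off dietary-intervention cost drivers: dietician visits plus
    one-way travel and parking per visit."""

    n_visits: float = 8.0
    fee_per_visit: float = 60.0
    km_to_dietician: float = 7.0
    cost_per_km: float = 0.19
    parking: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_visits", "fee_per_visit", "km_to_dietician",
                     "cost_per_km", "parking"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def intervention_cost_per_patient(i: InterventionCostInputs) -> float:
    """Cost of the intervention per patient: visits x (fee + travel +
    parking), with travel charged one way per visit."""
    return i.n_visits * (i.fee_per_visit
                         + i.km_to_dietician * i.cost_per_km + i.parking)


_WORK_BANDS = ("45-54", "55-64", "65+")


@dataclass
class ProductivityInputs:
    """Friction-cost-method inputs: employment shares by age band and graft
    status, the friction period, working hours, and sex-blended wages."""

    working_share_fg: dict = field(default_factory=lambda: {
        "45-54": 0.57, "55-64": 0.41, "65+": 0.06})
    working_share_gf: dict = field(default_factory=lambda: {
        "45-54": 0.32, "55-64": 0.19, "65+": 0.03})
    friction_days: float = 85.0
    workhours_per_day: float = 8.0
    male_wage: float = 37.90
    female_wage: float = 31.60
    male_share: float = 0.563
    hospital_days: float = 10.58

    def __post_init__(self) -> None:
        for band in _WORK_BANDS:
            fg, gf = self.working_share_fg[band], self.working_share_gf[band]
            if not (0.0 <= gf <= fg <= 1.0):
                raise ValueError(
                    f"working shares in band {band} must satisfy "
                    f"0 <= graft-failure ({gf}) <= functioning-graft ({fg}) <= 1")
        if not 0.0 <= self.male_share <= 1.0:
            raise ValueError("male_share must lie in [0, 1]")

    @staticmethod
    def band(age: float) -> str:
        # ages below 45 reuse the youngest tabulated band
        if age < 55:
            return "45-54"
        if age < 65:
            return "55-64"
        return "65+"

    def share_fg(self, age: float) -> float:
        return self.working_share_fg[self.band(age)]

    def share_gf(self, age: float) -> float:
        return self.working_share_gf[self.band(age)]


def blended_wage(p: ProductivityInputs) -> float:
    """Sex-blended hourly wage from the cohort's male share."""
    return p.male_share * p.male_wage + (1.0 - p.male_share) * p.female_wage


@dataclass
class UtilityInputs:
    """Health-state utilities; the dialysis state blends haemodialysis and
    peritoneal dialysis by their treatment shares."""

    u_fg: float = 0.81
    u_hd: float = 0.56
    u_pd: float = 0.58
    hd_share: float = 0.86
    u_death: float = 0.0
    discount_rate_effects: float = 0.015

    def __post_init__(self) -> None:
        for name in ("u_fg", "u_hd", "u_pd", "hd_share"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.u_death != 0.0:
            raise ValueError("u_death must be 0")


def dialysis_state_utility(u: UtilityInputs) -> float:
    """Utility of the graft-failure (dialysis) state: HD/PD-share-weighted
    mean of the two dialysis utilities."""
    return u.hd_share * u.u_hd + (1.0 - u.hd_share) * u.u_pd


@dataclass(frozen=True)
class GroupTotals:
    """Discounted lifetime totals for one adherence group's Markov trace."""

    diet: str
    group: int
    total_cost: float
    cost_by_category: dict
    total_qalys: float

    def __post_init__(self) -> None:
        cat_sum = sum(self.cost_by_category.values())
        scale = max(1.0, abs(self.total_cost))
        if abs(cat_sum - self.total_cost) > 1e-6 * scale:
            raise ValueError("cost_by_category does not sum to total_cost")


def accrue(trace: OccupancyTrace, costs: CostInputs, utilities: UtilityInputs,
           productivity: ProductivityInputs, diet: str, group: int,
           start_age: float, mid_cycle_discount: bool = True) -> GroupTotals:
    """Accrue discounted costs by category and QALYs over a trace.

    Per cycle t (cohort age start_age + t):

    * state accruals on the trapezoidal mean occupancy — transplant upkeep
      for FG1+FG2, dialysis upkeep for GF1+GF2, diet cost for FG states in
      groups 2-3 only (diet changes stop on dialysis), utilities;
    * event accruals on the transition counts — graft-failure cost on
      FG->GF moves, transplantation cost on re-transplant attempts
      (GF1->FG2 and GF1->GF2: the operation happened even on primary
      non-function), death cost on every move into Death, friction-method
      productivity loss on FG->GF moves with an equal-magnitude saving on
      GF1->FG2, and a hospital-stay productivity loss on re-transplants;
    * everything discounted at t + 0.5 (mid-cycle timing; set
      ``mid_cycle_discount=False`` for start-of-cycle discounting).
    """
    H = trace.horizon
    occ, counts = trace.occupancy, trace.transition_counts
    u_gf = dialysis_state_utility(utilities)
    wage = blended_wage(productivity)
    diet_cost = costs.diet_annual[diet][group]
    hours = productivity.workhours_per_day
    by_cat = dict.fromkeys(COST_CATEGORIES, 0.0)
    qalys = 0.0
    for t in range(H):
        age = start_age + t
        timing = t + 0.5 if mid_cycle_discount else float(t)
        df_c = (1.0 + costs.discount_rate_costs) ** -timing
        df_e = (1.0 + utilities.discount_rate_effects) ** -timing
        mean = 0.5 * (occ[t] + occ[t + 1])
        fg_mean = mean[FG1] + mean[FG2]
        gf_mean = mean[GF1] + mean[GF2]
        by_cat["transplant_upkeep"] += df_c * fg_mean * costs.transplant_upkeep
        by_cat["dialysis_upkeep"] += df_c * gf_mean * costs.dialysis_upkeep
        by_cat["diet"] += df_c * fg_mean * diet_cost
        qalys += df_e * (fg_mean * utilities.u_fg + gf_mean * u_gf)
        c = counts[t]
        gf_moves = c[FG1, GF1] + c[FG2, GF2]
        retx_moves = c[GF1, FG2] + c[GF1, GF2]
        deaths = c[FG1, DEATH] + c[GF1, DEATH] + c[FG2, DEATH] + c[GF2, DEATH]
        by_cat["graft_failure_events"] += (
            df_c * gf_moves * costs.graft_failure_event)
        by_cat["transplantation_events"] += (
            df_c * retx_moves * costs.transplantation_event)
        by_cat["death_events"] += df_c * deaths * costs.death_event
        share_gap = productivity.share_fg(age) - productivity.share_gf(age)
        friction_value = (share_gap * productivity.friction_days * hours * wage)
        hospital_loss = (productivity.share_fg(age)
                         * productivity.hospital_days * hours * wage)
        by_cat["productivity"] += df_c * (
            gf_moves * friction_value            # loss entering dialysis
            - c[GF1, FG2] * friction_value       # saving on return to work
            + retx_moves * hospital_loss)        # admission for the operation
    total_cost = sum(by_cat.values())
    return GroupTotals(diet=diet, group=group, total_cost=total_cost,
                       cost_by_category=by_cat, total_qalys=qalys)


@dataclass(frozen=True)
class AdherenceScenario:
    """Weights of the three adherence groups; intervention rows move the
    non-adherent remainder out of group 1 in equal halves to groups 2 and 3."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("adherence weights must be non-negative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError(
                f"adherence weights must sum to 1, got {self.w1 + self.w2 + self.w3}")

    @classmethod
    def no_intervention(cls) -> "AdherenceScenario":
        return cls(1.0, 0.0, 0.0)

    @classmethod
    def from_group1_share(cls, p: float) -> "AdherenceScenario":
        if not 0.0 <= p <= 1.0:
            raise ValueError("group-1 share must lie in [0, 1]")
        return cls(p, (1.0 - p) / 2.0, (1.0 - p) / 2.0)

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def mix_scenarios(groups: tuple[GroupTotals, GroupTotals, GroupTotals],
                  scenario: AdherenceScenario,
                  intervention_cost_total: float = 0.0
                  ) -> tuple[float, float]:
    """Adherence-weighted totals: cost and QALYs are the weighted sums of
    the three group traces; a one-off intervention cost (charged at model
    entry, hence undiscounted) is added on the cost side."""
    gs = sorted(groups, key=lambda g: g.group)
    if [g.group for g in gs] != [1, 2, 3]:
        raise ValueError("mix_scenarios needs exactly groups 1, 2 and 3")
    w = scenario.weights
    cost = sum(wi * g.total_cost for wi, g in zip(w, gs))
    qalys = sum(wi * g.total_qalys for wi, g in zip(w, gs))
    return cost + intervention_cost_total, qalys


def _truncate_toward_zero(x: float) -> int:
    return int(math.trunc(x))


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of the intervention mix against no
    intervention: ICER where defined, otherwise a dominance label.  ICERs
    are reported truncated toward zero to whole euros."""

    incremental_cost: float
    incremental_qalys: float
    icer_value: float | None
    label: str | None

    @property
    def reported(self) -> str:
        if self.label is not None:
            return self.label
        return str(_truncate_toward_zero(self.icer_value))


def icer(incremental_cost: float, incremental_qalys: float) -> CEAResult:
    """Classify an incremental (cost, QALY) pair.

    Negative cost with positive QALYs is "Dominant"; positive cost with
    negative QALYs is "Dominated"; zero QALY difference leaves the ratio
    undefined; otherwise the ICER is cost / QALYs.
    """
    if incremental_qalys == 0.0:
        return CEAResult(incremental_cost, incremental_qalys, None, "undefined")
    if incremental_cost < 0.0 and incremental_qalys > 0.0:
        return CEAResult(incremental_cost, incremental_qalys, None, "Dominant")
    if incremental_cost > 0.0 and incremental_qalys < 0.0:
        return CEAResult(incremental_cost, incremental_qalys, None, "Dominated")
    return CEAResult(incremental_cost, incremental_qalys,
                     incremental_cost / incremental_qalys, None)
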