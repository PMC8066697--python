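"""Budget impact of rolling the dietary intervention out nationally.

A payer-perspective, undiscounted calculation: every prevalent renal
transplant recipient receives the intervention at launch, every incident
recipient in each following year, over a short fixed horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BIAInputs:
    prevalent_patients: int = 11306
    annual_incidence: int = 904
    per_patient_cost: float = 514.64
    horizon_years: int = 5

    def __post_init__(self) -> None:
        if self.prevalent_patients < 0 or self.annual_incidence < 0:
            raise ValueError("patient counts must be non-negative")
        if self.horizon_years < 1:
            raise ValueError("horizon must be at least one year")
        if self.per_patient_cost < 0:
            raise ValueError("per-patient cost must be non-negative")


@dataclass(frozen=True)
class BIAResult:
    """Unrounded budget-impact totals; ``report()`` rounds to whole euros.

    Reporting convention: nearest euro (half-up) for the initial and total
    amounts, truncation toward zero for the recurring annual cost.
    """

    initial_cost: float
    annual_cost: float
    total_cost: float

    def report(self) -> dict[str, int]:
        half_up = lambda x: int(math.floor(x + 0.5))
        return {
            "initial_cost": half_up(self.initial_cost),
            "annual_cost": int(math.trunc(self.annual_cost)),
            "total_cost": half_up(self.total_cost),
        }


def budget_impact(inputs: BIAInputs) -> BIAResult:
    """initial = prevalent x per-patient cost; annual = incidence x
    per-patient cost; total = initial + horizon x annual.  No discounting."""
    initial = inputs.prevalent_patients * inputs.per_patient_cost
    annual = inputs.annual_incidence * inputs.per_patient_cost
    total = initial + inputs.horizon_years * annual
    return BIAResult(initial_cost=initial, annual_cost=annual,
                     total_cost=total)
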