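"""Five-state Markov cohort engine.

States, in fixed order: FG1 (first functioning graft), GF1 (first graft
failure, on dialysis), FG2 (functioning re-transplant), GF2 (second graft
failure), Death (absorbing).  Per-cycle 5x5 transition matrices are built
from annual event probabilities, dialysis mortality by age band, and an
age-dependent re-transplantation probability with a primary non-function
branch (GF1 -> GF2 in the same cycle as the transplant attempt).  The cohort
is propagated as expected state occupancy over a lifetime horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import AnnualProbabilityVector

STATES = ("FG1", "GF1", "FG2", "GF2", "Death")
FG1, GF1, FG2, GF2, DEATH = range(5)
STATE_INDEX = {name: i for i, name in enumerate(STATES)}

_ROW_TOL = 1e-12


class ScheduleConfigurationError(ValueError):
    """A cycle's off-diagonal probabilities exceed 1 (bad calibration)."""


@dataclass
class RetransplantParams:
    """Annual re-transplantation probability from dialysis, with a linear
    decline to zero between ``decline_start_age`` and ``zero_age``, and the
    probability that the new graft never functions (primary non-function)."""

    base_probability: float = 0.150
    decline_start_age: float = 65.0
    zero_age: float = 80.0
    primary_non_function: float = 0.007

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_probability <= 1.0:
            raise ValueError("base_probability must lie in [0, 1]")
        if not self.decline_start_age < self.zero_age:
            raise ValueError("decline_start_age must precede zero_age")
        if not 0.0 <= self.primary_non_function <= 1.0:
            raise ValueError("primary_non_function must lie in [0, 1]")


def retransplant_probability(age: float, params: RetransplantParams) -> float:
    """Re-transplantation probability at a given age: the base probability
    up to the decline start, linearly falling to zero at ``zero_age``."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if age <= params.decline_start_age:
        return params.base_probability
    if age >= params.zero_age:
        return 0.0
    frac = (params.zero_age - age) / (params.zero_age - params.decline_start_age)
    return params.base_probability * frac


_DEFAULT_DIALYSIS_BANDS = {
    "50-54": 0.040, "55-59": 0.052, "60-64": 0.076, "65-69": 0.102,
    "70-74": 0.138, "75-79": 0.190, "80-84": 0.240, "85+": 0.335,
}


@dataclass
class DialysisMortality:
    """Annual death probability on dialysis by age band; ages below the
    first band clamp to the first band's value."""

    bands: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIALYSIS_BANDS))

    def __post_init__(self) -> None:
        self._parse()  # validates bands eagerly

    def _parse(self) -> list[tuple[int, int | None, float]]:
        # parsed fresh on every lookup: sensitivity analyses mutate `bands`
        # in place, so no cached view may outlive a mutation
        parsed = []
        for key, q in self.bands.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"dialysis mortality {key}: {q} not in [0, 1]")
            if key.endswith("+"):
                lo, hi = int(key[:-1]), None
            else:
                lo_s, hi_s = key.split("-")
                lo, hi = int(lo_s), int(hi_s)
            parsed.append((lo, hi, float(q)))
        parsed.sort(key=lambda b: b[0])
        for (lo1, hi1, _), (lo2, _, _) in zip(parsed, parsed[1:]):
            if hi1 is None or hi1 + 1 != lo2:
                raise ValueError("dialysis mortality bands must be contiguous")
        return parsed

    def lookup(self, age: float) -> float:
        parsed = self._parse()
        a = int(np.floor(age))
        if a < parsed[0][0]:
            return parsed[0][2]
        for lo, hi, q in parsed:
            if hi is None or a <= hi:
                if a >= lo:
                    return q
        return parsed[-1][2]  # pragma: no cover


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle stochastic 5x5 matrices over the horizon, indexed by model
    time; the cohort is ``start_age + t`` years old during cycle t."""

    start_age: float
    matrices: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (5, 5):
            raise ValueError("matrices must have shape (H, 5, 5)")
        object.__setattr__(self, "matrices", m)

    @property
    def horizon(self) -> int:
        return int(self.matrices.shape[0])

    def validate(self) -> None:
        m = self.matrices
        if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
            raise ValueError("transition probabilities outside [0, 1]")
        row_sums = m.sum(axis=2)
        if np.any(np.abs(row_sums - 1.0) > _ROW_TOL):
            t, i = np.unravel_index(np.argmax(np.abs(row_sums - 1.0)),
                                    row_sums.shape)
            raise ValueError(
                f"row sum off by {row_sums[t, i] - 1.0:.3e} at cycle {t}, "
                f"state {STATES[i]}")
        death_rows = m[:, DEATH, :]
        expected = np.zeros(5); expected[DEATH] = 1.0
        if np.any(np.abs(death_rows - expected) > _ROW_TOL):
            raise ValueError("Death must be absorbing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.horizon):
            for i, src in enumerate(STATES):
                for j, dst in enumerate(STATES):
                    rows.append((t, self.start_age + t, src, dst,
                                 self.matrices[t, i, j]))
        return pd.DataFrame(rows, columns=["cycle", "age", "from_state",
                                           "to_state", "probability"])


def build_transition_schedule(dwfg: AnnualProbabilityVector,
                              gf: AnnualProbabilityVector,
                              dialysis: DialysisMortality,
                              retx: RetransplantParams,
                              start_age: float,
                              horizon: int) -> TransitionSchedule:
    """Assemble the per-cycle transition matrices.

    FG states lose mass to graft failure (gf[t]) and death (dwfg[t]); GF
    states lose mass to death on dialysis (by age); GF1 additionally sends
    re-transplanted patients to FG2 or, on primary non-function, straight to
    GF2.  Off-diagonal sums above 1 raise rather than being renormalised:
    silent renormalisation would mask a bad calibration.
    """
    if len(dwfg) < horizon or len(gf) < horizon:
        raise ValueError("probability vectors shorter than the horizon")
    mats = np.zeros((horizon, 5, 5))
    for t in range(horizon):
        age = start_age + t
        p_gf, p_d = float(gf.values[t]), float(dwfg.values[t])
        p_dial = dialysis.lookup(age)
        p_rtx = retransplant_probability(age, retx)
        pnf = retx.primary_non_function
        if p_gf + p_d > 1 + _ROW_TOL:
            raise ScheduleConfigurationError(
                f"cycle {t}, state FG1/FG2: graft failure {p_gf:.4f} + "
                f"death {p_d:.4f} exceed 1")
        if p_dial + p_rtx > 1 + _ROW_TOL:
            raise ScheduleConfigurationError(
                f"cycle {t}, state GF1: dialysis death {p_dial:.4f} + "
                f"re-transplant {p_rtx:.4f} exceed 1")
        m = mats[t]
        m[FG1, GF1], m[FG1, DEATH] = p_gf, p_d
        m[FG1, FG1] = 1.0 - p_gf - p_d
        m[GF1, FG2] = p_rtx * (1.0 - pnf)
        m[GF1, GF2] = p_rtx * pnf
        m[GF1, DEATH] = p_dial
        m[GF1, GF1] = 1.0 - p_rtx - p_dial
        m[FG2, GF2], m[FG2, DEATH] = p_gf, p_d
        m[FG2, FG2] = 1.0 - p_gf - p_d
        m[GF2, DEATH] = p_dial
        m[GF2, GF2] = 1.0 - p_dial
        m[DEATH, DEATH] = 1.0
    schedule = TransitionSchedule(start_age=start_age, matrices=mats)
    schedule.validate()
    return schedule


@dataclass(frozen=True)
class OccupancyTrace:
    """Expected state occupancy (persons) per cycle plus the expected number
    of persons moving along each transition in each cycle."""

    cohort_size: float
    occupancy: np.ndarray        # (H+1, 5)
    transition_counts: np.ndarray  # (H, 5, 5)

    @property
    def horizon(self) -> int:
        return int(self.transition_counts.shape[0])

    def residual_alive_fraction(self) -> float:
        """Fraction of the cohort not yet absorbed at the end of the
        horizon; a lifetime horizon should drive this to ~0."""
        return float(1.0 - self.occupancy[-1, DEATH] / self.cohort_size)

    def to_frame(self, start_age: float | None = None) -> pd.DataFrame:
        rows = []
        for t in range(self.occupancy.shape[0]):
            for i, state in enumerate(STATES):
                rows.append((t, None if start_age is None else start_age + t,
                             state, self.occupancy[t, i]))
        df = pd.DataFrame(rows, columns=["cycle", "age", "state", "occupancy"])
        return df.drop(columns=["age"]) if start_age is None else df

    def counts_to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.horizon):
            for i, src in enumerate(STATES):
                for j, dst in enumerate(STATES):
                    c = self.transition_counts[t, i, j]
                    if c != 0.0:
                        rows.append((t, src, dst, c))
        return pd.DataFrame(rows, columns=["cycle", "from_state", "to_state",
                                           "persons"])


def run_trace(schedule: TransitionSchedule, cohort_size: float = 1000.0,
              initial_state: str = "FG1") -> OccupancyTrace:
    """Propagate the cohort through the schedule.

    occupancy[t+1] = occupancy[t] @ M_t, starting with the whole cohort in
    ``initial_state``; transition_counts[t][i][j] = occupancy[t][i] * M_t[i][j].
    """
    if initial_state not in STATE_INDEX:
        raise ValueError(f"unknown initial state {initial_state!r}")
    H = schedule.horizon
    occ = np.zeros((H + 1, 5))
    occ[0, STATE_INDEX[initial_state]] = cohort_size
    counts = np.zeros((H, 5, 5))
    for t in range(H):
        counts[t] = occ[t][:, None] * schedule.matrices[t]
        occ[t + 1] = counts[t].sum(axis=0)
    return OccupancyTrace(cohort_size=cohort_size, occupancy=occ,
                          transition_counts=counts)
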