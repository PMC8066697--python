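"""Sensitivity analyses around the cost-effectiveness pipeline.

Deterministic (one-way) analysis re-runs the full pipeline at the lower and
upper 95% confidence limit of each parameter, holding the rest at base, and
ranks parameters into a tornado ordering.  Because the base case is
typically dominant (negative ICER), bars are ordered by the width of the
incremental net monetary benefit (NMB = wtp * dQALY - dCost) at the
willingness-to-pay threshold, which stays well-defined under dominance;
the ICERs at each limit are still reported.

Probabilistic analysis draws every parameter jointly from its assigned
distribution — beta for utilities and working shares, gamma for costs,
truncated normal for counts, durations and probabilities — and perturbs the
Weibull survival parameters on the log scale through the Cholesky factor of
each fit's covariance, rebuilding the annual probability vectors per draw.
Results feed a cost-effectiveness plane and acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, get_param, set_param
from .economics import icer
from .pipeline import DietCEA
from .survival import ENDPOINTS, GROUPS, cholesky_factor

FAMILIES = ("beta", "gamma", "normal")
Z95 = 1.96
ASSUMED_RELATIVE_SE = 0.25


class ParameterSpecError(ValueError):
    """A parameter's distribution cannot be built (infeasible moments)."""


@dataclass(frozen=True)
class ParameterSpec:
    """One scalar parameter of the model: where it lives (dotted config
    path), its base value, an optional printed 95% CI, its sampling family,
    and hard domain bounds."""

    name: str
    path: str
    base: float
    ci: tuple[float, float] | None = None
    family: str = "normal"
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterSpecError(f"{self.name}: unknown family {self.family!r}")
        if self.ci is not None and not self.ci[0] <= self.base <= self.ci[1]:
            raise ParameterSpecError(
                f"{self.name}: base {self.base} outside CI {self.ci}")


def derive_ci(spec: ParameterSpec) -> tuple[float, float]:
    """95% confidence limits: the printed range verbatim when present,
    otherwise base -/+ 1.96 * (25% of base), floored/capped at the domain
    bounds."""
    if spec.ci is not None:
        return spec.ci
    half = Z95 * ASSUMED_RELATIVE_SE * abs(spec.base)
    lo, hi = spec.base - half, spec.base + half
    bl, bh = spec.bounds
    if bl is not None:
        lo = max(lo, bl)
    if bh is not None:
        hi = min(hi, bh)
    return lo, hi


def standard_error(spec: ParameterSpec) -> float:
    """SE backed out of the printed CI (width / 2*1.96), else the assumed
    25% of the base value."""
    if spec.ci is not None:
        return (spec.ci[1] - spec.ci[0]) / (2.0 * Z95)
    return ASSUMED_RELATIVE_SE * abs(spec.base)


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """One draw from the parameter's distribution, moment-matched to
    (base, SE); zero SE returns the base exactly."""
    m, s = spec.base, standard_error(spec)
    if s == 0.0 or m == 0.0 and spec.family in ("gamma", "beta"):
        return m
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ParameterSpecError(
                f"{spec.name}: beta mean must lie strictly in (0, 1), got {m}")
        nu = m * (1.0 - m) / (s * s) - 1.0
        if nu <= 0.0:
            raise ParameterSpecError(
                f"{spec.name}: SE {s} too large for a beta on (0, 1) "
                f"with mean {m}")
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.family == "gamma":
        k = (m / s) ** 2
        theta = s * s / m
        return float(rng.gamma(k, theta))
    # truncated normal: resample into the domain bounds
    lo = spec.bounds[0] if spec.bounds[0] is not None else -np.inf
    hi = spec.bounds[1] if spec.bounds[1] is not None else np.inf
    for _ in range(1000):
        x = float(rng.normal(m, s))
        if lo <= x <= hi:
            return x
    raise ParameterSpecError(
        f"{spec.name}: truncated-normal sampling failed to land in "
        f"[{lo}, {hi}]")


def sample_parameters(specs: Sequence[ParameterSpec],
                      rng: np.random.Generator | int) -> dict[str, float]:
    """One joint draw: every spec sampled independently (correlation enters
    only through the Weibull Cholesky draws, handled by the PSA driver)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return {spec.path: sample_parameter(spec, rng) for spec in specs}


# ---------------------------------------------------------------------------
# default parameter book

def _spec(name, path, config, family, bounds=(None, None)) -> ParameterSpec:
    base = float(get_param(config, path))
    ci = config.param_cis.get(path)
    return ParameterSpec(name=name, path=path, base=base,
                         ci=tuple(ci) if ci else None, family=family,
                         bounds=bounds)


def default_parameter_specs(config: ModelConfig, diet: str,
                            include_probability_factors: bool = True
                            ) -> list[ParameterSpec]:
    """The model's parameter book for one diet.

    ``include_probability_factors`` adds multiplicative factors on the
    extrapolated per-group DWFG / graft-failure probability vectors (base
    1.0); the one-way analysis varies those, while the probabilistic
    analysis leaves them out and perturbs the Weibull fits through their
    Cholesky factors instead.
    """
    specs: list[ParameterSpec] = []
    unit = (0.0, 1.0)
    pos = (0.0, None)
    for name, path in (("Utility functioning graft", "utilities.u_fg"),
                       ("Utility haemodialysis", "utilities.u_hd"),
                       ("Utility peritoneal dialysis", "utilities.u_pd")):
        specs.append(_spec(name, path, config, "beta", unit))
    for band in ("45-54", "55-64", "65+"):
        specs.append(_spec(f"Working share FG {band}",
                           f"productivity.working_share_fg.{band}",
                           config, "beta", unit))
        specs.append(_spec(f"Working share GF {band}",
                           f"productivity.working_share_gf.{band}",
                           config, "beta", unit))
    for name, path in (("Dialysis upkeep", "costs.dialysis_upkeep"),
                       ("Transplantation upkeep", "costs.transplant_upkeep"),
                       ("Transplantation", "costs.transplantation_event"),
                       ("Death", "costs.death_event"),
                       ("Renal graft failure", "costs.graft_failure_event"),
                       ("Cost per dietician visit",
                        "intervention.fee_per_visit")):
        specs.append(_spec(name, path, config, "gamma", pos))
    for group in (2, 3):
        specs.append(_spec(f"Diet cost group {group}",
                           f"costs.diet_annual.{diet}.{group}",
                           config, "gamma", pos))
    specs.append(_spec("Number of dietician visits", "intervention.n_visits",
                       config, "normal", pos))
    specs.append(_spec("Days in hospital", "productivity.hospital_days",
                       config, "normal", pos))
    specs.append(_spec("Re-transplantation probability",
                       "retransplant.base_probability", config, "normal", unit))
    specs.append(_spec("Primary non-function",
                       "retransplant.primary_non_function", config,
                       "normal", unit))
    for band in ("50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
                 "80-84", "85+"):
        specs.append(_spec(f"Death on dialysis {band}",
                           f"dialysis_mortality.bands.{band}",
                           config, "normal", unit))
    if include_probability_factors:
        label = {"dwfg": "DWFG", "graft_failure": "GF"}
        for endpoint in ENDPOINTS:
            for group in GROUPS:
                specs.append(_spec(
                    f"Group {group} {label[endpoint]} probability",
                    f"prob_factors.{endpoint}.{group}", config, "normal", pos))
    return specs


# ---------------------------------------------------------------------------
# deterministic one-way analysis

@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: the pipeline outcome with the parameter at each 95%
    confidence limit, everything else at base."""

    name: str
    path: str
    low_value: float
    high_value: float
    low_result: dict
    high_result: dict
    width: float
    failed: bool = False


def _outcome(model: DietCEA, p_group1: float, wtp: float) -> dict:
    dc, dq = model.incremental(p_group1)
    res = icer(dc, dq)
    return {"incremental_cost": dc, "incremental_qalys": dq,
            "icer": res.reported, "nmb": wtp * dq - dc}


def run_dsa(model: DietCEA, specs: Sequence[ParameterSpec],
            wtp: float | None = None, p_group1: float = 0.0
            ) -> list[TornadoEntry]:
    """One-way sensitivity analysis: for each parameter the full pipeline
    is re-run at its lower and upper confidence limit; entries are sorted
    by descending NMB bar width.  A pipeline failure at a limit flags the
    entry instead of dropping it."""
    if wtp is None:
        wtp = model.config.wtp
    entries = []
    for spec in specs:
        lo, hi = derive_ci(spec)
        results, failed = [], False
        for value in (lo, hi):
            cfg = model.config.copy()
            set_param(cfg, spec.path, value)
            try:
                results.append(_outcome(model.with_config(cfg), p_group1, wtp))
            except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                results.append({"error": str(exc)})
                failed = True
        width = (abs(results[1]["nmb"] - results[0]["nmb"])
                 if not failed else float("nan"))
        entries.append(TornadoEntry(name=spec.name, path=spec.path,
                                    low_value=lo, high_value=hi,
                                    low_result=results[0],
                                    high_result=results[1],
                                    width=width, failed=failed))
    entries.sort(key=lambda e: (not e.failed, e.width), reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append({
            "parameter": e.name, "path": e.path,
            "low_value": e.low_value, "high_value": e.high_value,
            "nmb_low": e.low_result.get("nmb"),
            "nmb_high": e.high_result.get("nmb"),
            "icer_low": e.low_result.get("icer"),
            "icer_high": e.high_result.get("icer"),
            "width": e.width, "failed": e.failed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic analysis

@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo cloud of incremental (cost, QALY) pairs; reproducible
    from the stored seed."""

    iterations: int
    pairs: np.ndarray  # (iterations, 2): delta cost, delta QALYs
    seed: int
    failures: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.iterations),
            "delta_cost": self.pairs[:, 0],
            "delta_qalys": self.pairs[:, 1],
        })


def run_psa(model: DietCEA, specs: Sequence[ParameterSpec],
            iterations: int | None = None, seed: int | None = None,
            p_group1: float = 0.0, perturb_survival: bool = True) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Each iteration draws every scalar parameter from its distribution and
    the six (group, endpoint) Weibull log-parameter pairs through their
    Cholesky factors, reruns the pipeline, and stores the incremental
    (cost, QALY) pair.  Iteration failures are recorded with their draw and
    the run continues.  ``perturb_survival=False`` freezes the survival
    fits at their point estimates (useful for degenerate-variance checks).
    """
    cfg = model.config
    if iterations is None:
        iterations = cfg.psa_iterations
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    factors = {(g, ep): cholesky_factor(model.fits[g][ep])
               for g in GROUPS for ep in ENDPOINTS}
    log_params = {(g, ep): model.fits[g][ep].log_params
                  for g in GROUPS for ep in ENDPOINTS}
    pairs = np.empty((iterations, 2))
    failures = []
    for it in range(iterations):
        draw = sample_parameters(specs, rng)
        overrides = {}
        for key, L in factors.items():
            z = rng.standard_normal(2)
            if perturb_survival:
                shape, scale = np.exp(log_params[key] + L @ z)
                overrides[key] = (float(shape), float(scale))
        cfg_i = cfg.copy()
        for path, value in draw.items():
            set_param(cfg_i, path, value)
        try:
            m = model.with_config(cfg_i)
            pairs[it] = m.incremental(
                p_group1, totals=m.all_group_totals(weibull_overrides=overrides))
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            pairs[it] = np.nan
            failures.append((it, draw, str(exc)))
    return PSAResult(iterations=iterations, pairs=pairs, seed=seed,
                     failures=tuple(failures))


def default_wtp_grid() -> np.ndarray:
    """0 to 80,000 EUR/QALY in 500-EUR steps (anchored at the 20,000
    threshold)."""
    return np.arange(0.0, 80000.0 + 1, 500.0)


def ceac(result: PSAResult, wtp_grid: Sequence[float] | None = None
         ) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each willingness-to-pay
    lambda, the fraction of pairs with positive net monetary benefit
    lambda * dQALY - dCost > 0."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("the willingness-to-pay grid must be non-empty")
    ok = np.all(np.isfinite(result.pairs), axis=1)
    pairs = result.pairs[ok]
    nmb = wtp_grid[:, None] * pairs[None, :, 1] - pairs[None, :, 0]
    prob = (nmb > 0).mean(axis=1) if pairs.size else np.zeros_like(wtp_grid)
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": prob})


def probability_cost_effective(result: PSAResult, wtp: float) -> float:
    """Fraction of PSA iterations cost-effective at one threshold."""
    ok = np.all(np.isfinite(result.pairs), axis=1)
    pairs = result.pairs[ok]
    if pairs.size == 0:
        return 0.0
    return float((wtp * pairs[:, 1] - pairs[:, 0] > 0).mean())
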