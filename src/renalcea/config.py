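"""Model configuration: a machine-readable mirror of the published
parameter tables.

The configuration bundles every parameter block the pipeline needs — costs,
utilities, productivity, intervention, re-transplantation, dialysis
mortality, discounting, cohort settings, adherence scenarios, and the
printed 95% confidence ranges used by the sensitivity analyses — with a
strict YAML round trip (unknown keys rejected, invariants validated at
load).  Parameters are addressable by dotted path (e.g.
``costs.dialysis_upkeep``, ``productivity.working_share_fg.45-54``) so the
sensitivity analyses can perturb any of them generically.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
from dataclasses import dataclass, field, is_dataclass

import yaml

from .economics import (CostInputs, InterventionCostInputs, ProductivityInputs,
                        UtilityInputs)
from .markov import DialysisMortality, RetransplantParams


class ConfigError(ValueError):
    """Configuration rejected: names the offending key and constraint."""


# Printed 95% confidence ranges, keyed by parameter path.  Paths without a
# printed range fall back to the assumed SE of 25% of the base value.
DEFAULT_CIS: dict[str, tuple[float, float]] = {
    "utilities.u_fg": (0.72, 0.90),
    "utilities.u_hd": (0.49, 0.62),
    "utilities.u_pd": (0.50, 0.67),
    "costs.dialysis_upkeep": (44806.0, 130904.0),
    "costs.transplant_upkeep": (5518.0, 16122.0),
    "costs.transplantation_event": (30574.0, 89324.0),
    "costs.death_event": (594.0, 1736.0),
    "costs.graft_failure_event": (1222.0, 3572.0),
    "costs.diet_annual.dash.2": (93.08, 271.93),
    "costs.diet_annual.dash.3": (186.15, 543.85),
    "costs.diet_annual.potassium.2": (38.68, 113.00),
    "costs.diet_annual.potassium.3": (86.43, 252.51),
    "intervention.n_visits": (2.7, 13.2),
    "intervention.fee_per_visit": (30.60, 89.40),
    "productivity.working_share_fg.45-54": (0.29, 0.85),
    "productivity.working_share_fg.55-64": (0.21, 0.61),
    "productivity.working_share_fg.65+": (0.03, 0.09),
    "productivity.working_share_gf.45-54": (0.16, 0.48),
    "productivity.working_share_gf.55-64": (0.10, 0.28),
    "productivity.working_share_gf.65+": (0.01, 0.04),
    "productivity.hospital_days": (5.40, 15.80),
    "retransplant.base_probability": (0.077, 0.224),
    "retransplant.primary_non_function": (0.004, 0.011),
    "dialysis_mortality.bands.50-54": (0.035, 0.046),
    "dialysis_mortality.bands.55-59": (0.045, 0.058),
    "dialysis_mortality.bands.60-64": (0.069, 0.083),
    "dialysis_mortality.bands.65-69": (0.093, 0.110),
    "dialysis_mortality.bands.70-74": (0.127, 0.150),
    "dialysis_mortality.bands.75-79": (0.176, 0.205),
    "dialysis_mortality.bands.80-84": (0.219, 0.262),
    "dialysis_mortality.bands.85+": (0.297, 0.373),
}

_DEFAULT_SHARES = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9


@dataclass
class ModelConfig:
    """Everything the pipeline needs to run, with validated defaults equal
    to the published parameter tables."""

    start_age: float = 53.0
    horizon: int = 57
    cohort_size: float = 1000.0
    wtp: float = 20000.0
    psa_iterations: int = 10000
    seed: int = 12345
    mid_cycle_discount: bool = True
    group1_shares: list = field(default_factory=lambda: list(_DEFAULT_SHARES))
    costs: CostInputs = field(default_factory=CostInputs)
    intervention: InterventionCostInputs = field(
        default_factory=InterventionCostInputs)
    productivity: ProductivityInputs = field(default_factory=ProductivityInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    retransplant: RetransplantParams = field(default_factory=RetransplantParams)
    dialysis_mortality: DialysisMortality = field(
        default_factory=DialysisMortality)
    prob_factors: dict = field(default_factory=lambda: {
        "dwfg": {1: 1.0, 2: 1.0, 3: 1.0},
        "graft_failure": {1: 1.0, 2: 1.0, 3: 1.0},
    })
    param_cis: dict = field(default_factory=lambda: dict(DEFAULT_CIS))

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


def default_config() -> ModelConfig:
    cfg = ModelConfig()
    validate_config(cfg)
    return cfg


def get_param(config: ModelConfig, path: str):
    obj = config
    for part in path.split("."):
        if is_dataclass(obj):
            if not hasattr(obj, part):
                raise ConfigError(f"unknown parameter path {path!r} at {part!r}")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            key = part
            if key not in obj:
                try:
                    key = int(part)
                except ValueError:
                    pass
            if key not in obj:
                raise ConfigError(f"unknown parameter path {path!r} at {part!r}")
            obj = obj[key]
        else:
            raise ConfigError(f"cannot traverse {path!r} past {part!r}")
    return obj


def set_param(config: ModelConfig, path: str, value: float) -> None:
    """Set one scalar parameter by dotted path, in place."""
    parts = path.split(".")
    obj = config
    for part in parts[:-1]:
        if is_dataclass(obj):
            if not hasattr(obj, part):
                raise ConfigError(f"unknown parameter path {path!r} at {part!r}")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            key = part if part in obj else _try_int(part)
            if key not in obj:
                raise ConfigError(f"unknown parameter path {path!r} at {part!r}")
            obj = obj[key]
        else:
            raise ConfigError(f"cannot traverse {path!r} past {part!r}")
    last = parts[-1]
    if is_dataclass(obj):
        if not hasattr(obj, last):
            raise ConfigError(f"unknown parameter path {path!r} at {last!r}")
        setattr(obj, last, value)
    elif isinstance(obj, dict):
        key = last if last in obj else _try_int(last)
        if key not in obj:
            raise ConfigError(f"unknown parameter path {path!r} at {last!r}")
        obj[key] = value
    else:
        raise ConfigError(f"cannot set {path!r} on {type(obj).__name__}")


def _try_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


_BLOCKS = {
    "costs": CostInputs,
    "intervention": InterventionCostInputs,
    "productivity": ProductivityInputs,
    "utilities": UtilityInputs,
    "retransplant": RetransplantParams,
    "dialysis_mortality": DialysisMortality,
}
_SCALARS = ("start_age", "horizon", "cohort_size", "wtp", "psa_iterations",
            "seed", "mid_cycle_discount")


def config_to_dict(config: ModelConfig) -> dict:
    out: dict = {name: getattr(config, name) for name in _SCALARS}
    out["group1_shares"] = list(config.group1_shares)
    for name in _BLOCKS:
        out[name] = dataclasses.asdict(getattr(config, name))
    out["prob_factors"] = copy.deepcopy(config.prob_factors)
    out["param_cis"] = {k: list(v) for k, v in config.param_cis.items()}
    return out


def config_from_dict(data: dict) -> ModelConfig:
    known = set(_SCALARS) | set(_BLOCKS) | {
        "group1_shares", "prob_factors", "param_cis"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name in _SCALARS + ("group1_shares",):
        if name in data:
            kwargs[name] = data[name]
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name]
            fields = {f.name for f in dataclasses.fields(cls)}
            extra = set(block) - fields
            if extra:
                raise ConfigError(f"{name}: unknown keys {sorted(extra)}")
            try:
                kwargs[name] = cls(**block)
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"{name}: {exc}") from exc
    if "prob_factors" in data:
        kwargs["prob_factors"] = {
            ep: {int(g): float(v) for g, v in by_group.items()}
            for ep, by_group in data["prob_factors"].items()}
    if "param_cis" in data:
        kwargs["param_cis"] = {k: tuple(v) for k, v in data["param_cis"].items()}
    cfg = ModelConfig(**kwargs)
    validate_config(cfg)
    return cfg


def validate_config(config: ModelConfig) -> None:
    if config.start_age < 0:
        raise ConfigError("start_age: must be non-negative")
    if config.horizon < 1:
        raise ConfigError("horizon: must be at least one cycle")
    if config.cohort_size <= 0:
        raise ConfigError("cohort_size: must be positive")
    if config.wtp < 0:
        raise ConfigError("wtp: must be non-negative")
    if config.psa_iterations < 1:
        raise ConfigError("psa_iterations: must be at least 1")
    for p in config.group1_shares:
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"group1_shares: {p} outside [0, 1]")
    for ep, by_group in config.prob_factors.items():
        if ep not in ("dwfg", "graft_failure"):
            raise ConfigError(f"prob_factors: unknown endpoint {ep!r}")
        for g, v in by_group.items():
            if v < 0:
                raise ConfigError(f"prob_factors.{ep}.{g}: must be non-negative")
    for path, (lo, hi) in config.param_cis.items():
        base = get_param(config, path)
        if not lo <= base <= hi:
            raise ConfigError(
                f"param_cis.{path}: base value {base} outside printed "
                f"range ({lo}, {hi})")


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("configuration file must contain a mapping")
    return config_from_dict(data)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: ModelConfig) -> str:
    """SHA-256 of the canonical YAML serialisation (for run logs)."""
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
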