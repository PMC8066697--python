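"""Survival analysis feeding the Markov cohort model.

Right-censored time-to-event data for renal transplant recipients are fitted
with Weibull distributions (one fit per diet-adherence group and endpoint:
death with a functioning graft, or graft failure).  The fitted survival
curves are extrapolated over the model horizon and converted into annual
transition probabilities.  Extrapolated death probabilities are forced to
converge with general-population background mortality once the curves cross.
The fit covariance, expressed on the (log shape, log scale) scale, drives
correlated parameter draws in the probabilistic sensitivity analysis via its
Cholesky factor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, WeibullFitter
from lifelines.exceptions import ConvergenceError

ENDPOINTS = ("dwfg", "graft_failure")
DIETS = ("dash", "potassium")
GROUPS = (1, 2, 3)


class SurvivalInputError(ValueError):
    """Invalid survival dataset (bad labels, non-positive times, ...)."""


class FitError(RuntimeError):
    """Weibull fit impossible (no events) or did not converge."""


class NumericalError(ArithmeticError):
    """Non-finite quantity encountered (survival underflow, bad ratio)."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored event times for one endpoint in one diet group.

    ``times`` are years since transplantation (strictly positive); ``events``
    is True where the endpoint was observed and False where the record was
    censored (administratively, at random, or by the competing endpoint).
    """

    endpoint: str
    diet: str
    group: int
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise SurvivalInputError(
                f"endpoint {self.endpoint!r} not in {ENDPOINTS}")
        if self.diet not in DIETS:
            raise SurvivalInputError(f"diet {self.diet!r} not in {DIETS}")
        if self.group not in GROUPS:
            raise SurvivalInputError(f"group {self.group!r} not in {GROUPS}")
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        if times.ndim != 1 or events.shape != times.shape:
            raise SurvivalInputError("times and events must be 1-d and aligned")
        if times.size and (not np.all(np.isfinite(times)) or np.any(times <= 0)):
            raise SurvivalInputError("times must be strictly positive and finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_records(cls, endpoint: str, diet: str, group: int,
                     records: Iterable[tuple[float, bool]]) -> "SurvivalDataset":
        recs = list(records)
        times = np.array([t for t, _ in recs], dtype=float)
        events = np.array([bool(e) for _, e in recs], dtype=bool)
        return cls(endpoint, diet, group, times, events)


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit survival estimate: step function S(t) at observed times."""

    times: np.ndarray
    survival: np.ndarray
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S = 1 before the
        first observed time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def steps(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.survival.tolist()))


def kaplan_meier(data: SurvivalDataset) -> KaplanMeierEstimate:
    """Kaplan–Meier product-limit estimate of the survival function.

    With every record censored the estimate is identically 1 and the
    ``all_censored`` flag is set so that downstream fitting can refuse it.
    """
    if len(data) == 0:
        raise SurvivalInputError("cannot estimate survival from an empty dataset")
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, event_observed=data.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row; S(0)=1 is implicit
    return KaplanMeierEstimate(times=times[keep], survival=surv[keep],
                               all_censored=data.n_events == 0)


def weibull_log_likelihood(log_shape: float, log_scale: float,
                           times: np.ndarray, events: np.ndarray) -> float:
    """Censored-Weibull log-likelihood at (log shape, log scale).

    Events contribute log hazard + log survival, censored records log
    survival only.  Kept independent of lifelines so it can serve as an
    oracle (grid searches, information-matrix differentiation).
    """
    k = np.exp(log_shape)
    s = np.exp(log_scale)
    z = np.asarray(times, dtype=float) / s
    ev = np.asarray(events, dtype=bool)
    with np.errstate(divide="ignore"):
        log_hazard = np.log(k / s) + (k - 1.0) * np.log(z)
    return float(np.sum(log_hazard[ev]) - np.sum(z ** k))


@dataclass(frozen=True)
class WeibullFit:
    """Weibull survival fit: S(t) = exp(-(t/scale)^shape).

    ``covariance`` is the 2x2 covariance of (log shape, log scale), the
    inverse of the numerically differentiated observed information at the
    maximum-likelihood estimate.
    """

    shape: float
    scale: float
    log_likelihood: float
    aic: float
    bic: float
    covariance: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise FitError("shape and scale must be positive")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise FitError("covariance must be 2x2")
        object.__setattr__(self, "covariance", cov)

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale) ** self.shape))

    @property
    def log_params(self) -> np.ndarray:
        return np.array([np.log(self.shape), np.log(self.scale)])


def _observed_information_covariance(times: np.ndarray, events: np.ndarray,
                                     log_shape: float, log_scale: float,
                                     eig_floor: float = 1e-12) -> np.ndarray:
    """Inverse observed information on the log-parameter scale, by central
    finite differences of the log-likelihood; eigenvalues floored for PSD."""
    x0 = np.array([log_shape, log_scale])
    h = 1e-5 * np.maximum(1.0, np.abs(x0))

    def ll(x: np.ndarray) -> float:
        return weibull_log_likelihood(x[0], x[1], times, events)

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.zeros(2); e_i[i] = h[i]
            e_j = np.zeros(2); e_j[j] = h[j]
            hess[i, j] = (
                ll(x0 + e_i + e_j) - ll(x0 + e_i - e_j)
                - ll(x0 - e_i + e_j) + ll(x0 - e_i - e_j)
            ) / (4.0 * h[i] * h[j])
    info = -0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if np.any(w < eig_floor):
        cov = (v * np.maximum(w, eig_floor)) @ v.T
    return cov


def fit_weibull(data: SurvivalDataset,
                fixed_shape: float | None = None) -> WeibullFit:
    """Maximum-likelihood Weibull fit under right censoring.

    With ``fixed_shape`` the scale has a closed form,
    scale = (sum(t_i^k) / d)^(1/k) with d the event count (the exponential
    MLE when k = 1); otherwise lifelines' WeibullFitter does the
    optimisation.  AIC/BIC use two free parameters and n = record count.
    """
    if data.n_events == 0:
        raise FitError(
            f"no events in {data.diet}/group {data.group}/{data.endpoint}: "
            "a Weibull fit requires at least one observed event")
    times, events = data.times, data.events
    if fixed_shape is not None:
        k = float(fixed_shape)
        scale = float((np.sum(times ** k) / data.n_events) ** (1.0 / k))
        shape = k
    else:
        wf = WeibullFitter()
        try:
            wf.fit(times, event_observed=events)
        except ConvergenceError as exc:  # pragma: no cover - data dependent
            raise FitError(f"Weibull fit did not converge: {exc}") from exc
        shape = float(wf.rho_)
        scale = float(wf.lambda_)
    ll = weibull_log_likelihood(np.log(shape), np.log(scale), times, events)
    n = len(data)
    cov = _observed_information_covariance(times, events,
                                           np.log(shape), np.log(scale))
    return WeibullFit(shape=shape, scale=scale, log_likelihood=ll,
                      aic=2 * 2 - 2 * ll, bic=2 * np.log(n) - 2 * ll,
                      covariance=cov, n=n)


@dataclass(frozen=True)
class AnnualProbabilityVector:
    """Per-cycle transition probabilities p_t = 1 - S(t+1)/S(t) for one
    endpoint in one group; ``converged_from`` marks the first cycle at which
    background mortality replaced the extrapolation (death endpoint only)."""

    endpoint: str
    group: int
    values: np.ndarray
    converged_from: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
            raise NumericalError("annual probabilities must be finite in [0, 1]")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


def weibull_annual_probs(shape: float, scale: float, horizon: int) -> np.ndarray:
    """Annual event probabilities 1 - S(t+1)/S(t) of a Weibull survival
    curve, computed on the cumulative-hazard scale so the survival ratio
    never underflows: p_t = 1 - exp(H(t) - H(t+1))."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    t = np.arange(horizon, dtype=float)
    cumhaz = (t / scale) ** shape
    cumhaz_next = ((t + 1.0) / scale) ** shape
    p = 1.0 - np.exp(cumhaz - cumhaz_next)
    if np.any(~np.isfinite(p)):
        raise NumericalError(
            f"non-finite annual probability for shape={shape}, scale={scale}")
    return np.clip(p, 0.0, 1.0)


def annual_transition_probs(fit: WeibullFit, horizon: int,
                            endpoint: str = "dwfg",
                            group: int = 1) -> AnnualProbabilityVector:
    """Annual transition probabilities over the model horizon from a fitted
    Weibull survival curve."""
    values = weibull_annual_probs(fit.shape, fit.scale, horizon)
    return AnnualProbabilityVector(endpoint=endpoint, group=group,
                                   values=values, converged_from=None)


@dataclass(frozen=True)
class MortalityTable:
    """Background life table: annual death probability q by integer age.

    Lookups outside the tabulated range clamp to the nearest endpoint.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.ndim != 1 or q.shape != ages.shape or ages.size == 0:
            raise ValueError("life table needs aligned, non-empty age/q columns")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("life-table q must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    def lookup(self, age: float) -> float:
        a = int(np.floor(age))
        a = min(max(a, int(self.ages[0])), int(self.ages[-1]))
        idx = int(np.searchsorted(self.ages, a, side="right")) - 1
        return float(self.q[idx])

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        df = pd.read_csv(path)
        missing = {"age", "q_annual"} - set(df.columns)
        if missing:
            raise ValueError(f"life-table CSV missing columns {sorted(missing)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["q_annual"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "q_annual": self.q}).to_csv(
            path, index=False)

    @classmethod
    def gompertz_makeham(cls, makeham: float = 5e-4, level: float = 1.677e-5,
                         slope: float = 0.1, max_age: int = 110
                         ) -> "MortalityTable":
        """Synthetic background life table from a Gompertz–Makeham hazard
        h(a) = makeham + level * exp(slope * a), q = 1 - exp(-h).

        A synthetic stand-in calibrated to the order of magnitude of Dutch
        adult mortality (q ~ 0.004 at 53, ~0.05 at 80); replace with a real
        national life table via :meth:`from_csv` for applied work.
        """
        ages = np.arange(0, max_age + 1)
        hazard = makeham + level * np.exp(slope * ages)
        return cls(ages, 1.0 - np.exp(-hazard))


def apply_background_convergence(probs: AnnualProbabilityVector,
                                 table: MortalityTable,
                                 start_age: float) -> AnnualProbabilityVector:
    """Converge an extrapolated death-probability vector with background
    mortality.

    From the first cycle where the extrapolated probability falls below the
    background probability for the cohort's age at that cycle, the value is
    replaced by the background probability (the maximum of the two
    thereafter, so the vector never dips below background again); earlier
    cycles are untouched.  No crossing leaves the vector unchanged with
    ``converged_from = None``.
    """
    if probs.endpoint != "dwfg":
        raise ValueError(
            "background convergence applies to the death (DWFG) endpoint only")
    background = np.array([table.lookup(start_age + t)
                           for t in range(len(probs))])
    below = probs.values < background
    if not np.any(below):
        return dataclasses.replace(probs, converged_from=None)
    idx = int(np.argmax(below))
    values = probs.values.copy()
    values[idx:] = np.maximum(values[idx:], background[idx:])
    return dataclasses.replace(probs, values=values, converged_from=idx)


def cholesky_factor(fit_or_cov) -> np.ndarray:
    """Lower-triangular Cholesky factor L with L @ L.T equal to the fit's
    log-parameter covariance; near-PSD matrices are repaired by flooring
    eigenvalues at 1e-12 before a final attempt."""
    cov = fit_or_cov.covariance if isinstance(fit_or_cov, WeibullFit) \
        else np.asarray(fit_or_cov, dtype=float)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        sym = 0.5 * (cov + cov.T)
        w, v = np.linalg.eigh(sym)
        # repair only round-off-level negativity; genuinely indefinite
        # matrices are a modelling error, not a numerical one
        if w.min() < -1e-8 * max(1.0, float(w.max())):
            raise ValueError(
                f"covariance is not positive semi-definite: {cov!r}") from exc
        return np.linalg.cholesky((v * np.maximum(w, 1e-12)) @ v.T)


# ---------------------------------------------------------------------------
# CSV dialect: patient_id, diet, group, endpoint, time_years, event

def read_survival_csv(path) -> dict[tuple[str, int, str], SurvivalDataset]:
    """Read patient-level survival records; returns datasets keyed by
    (diet, group, endpoint)."""
    df = pd.read_csv(path)
    required = {"patient_id", "diet", "group", "endpoint", "time_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SurvivalInputError(f"survival CSV missing columns {sorted(missing)}")
    out: dict[tuple[str, int, str], SurvivalDataset] = {}
    for (diet, group, endpoint), sub in df.groupby(["diet", "group", "endpoint"],
                                                   sort=True):
        out[(str(diet), int(group), str(endpoint))] = SurvivalDataset(
            endpoint=str(endpoint), diet=str(diet), group=int(group),
            times=sub["time_years"].to_numpy(dtype=float),
            events=sub["event"].to_numpy(dtype=int).astype(bool))
    return out


def write_survival_csv(datasets: Mapping[tuple[str, int, str], SurvivalDataset]
                       | Sequence[SurvivalDataset], path) -> None:
    if isinstance(datasets, Mapping):
        datasets = list(datasets.values())
    rows = []
    pid = 0
    for ds in datasets:
        for t, e in zip(ds.times, ds.events):
            rows.append((pid, ds.diet, ds.group, ds.endpoint,
                         float(t), int(e)))
            pid += 1
    pd.DataFrame(rows, columns=["patient_id", "diet", "group", "endpoint",
                                "time_years", "event"]).to_csv(path, index=False)
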