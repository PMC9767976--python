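"""Deterministic (tornado) and probabilistic sensitivity analysis.

The one-way analysis moves each parameter to its low and high bound with all
others at base and records the ICER; the probabilistic analysis jointly samples
every non-fixed parameter (beta for utilities and other probabilities, gamma
for costs, hyperparameters moment-matched so the mean equals the base value and
the standard deviation is (high - low) / (2 * 1.96)) and summarizes the
iterations as a cost-effectiveness acceptability curve.

Random-number streams: one master seed spawns an independent substream per
parameter, so adding or removing a parameter does not perturb the draws of the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .economics import (CEAResult, CostSettings, DosingSchedule, EconomicInputs,
                        Param, StrategyResult, accumulate_costs, accumulate_qalys)
from .psm import build_grid, expected_time, state_occupancy
from .survival import ParametricSurvival

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "CEAEvaluator",
    "build_param_specs",
    "apply_overrides",
    "sample_params",
    "owsa",
    "run_psa",
    "ceac",
    "ceac_crossing",
]


@dataclass(frozen=True)
class ParamSpec:
    """One tunable input: base value, deterministic range, PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    dist: str = "fixed"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: range [{self.low}, {self.high}] "
                             f"must bracket base {self.base}")
        if self.dist == "beta" and not 0.0 <= self.base <= 1.0:
            raise ValueError(f"{self.name}: beta requires a base in [0, 1]")


def build_param_specs(
    inputs: EconomicInputs,
    discount_rate: float = 0.05,
    discount_range: tuple[float, float] = (0.0, 0.08),
    include_discount: bool = True,
) -> list[ParamSpec]:
    """Enumerate the sensitivity parameters of an economic-input set.

    Parameters without a printed range default to +/-20 % of base.  Shares are
    treated as beta-distributed probabilities.
    """
    specs: list[ParamSpec] = []

    def add(name: str, p: Param, dist: str | None = None):
        lo, hi = p.bounds()
        specs.append(ParamSpec(name, p.value, lo, hi, dist or p.dist))

    for drug, dp in inputs.drug_prices.items():
        add(f"price.{drug}", dp.price)
    for key, p in inputs.unit_costs.items():
        add(f"cost.{key}", p, p.dist if p.dist != "fixed" else "gamma")
    for ev, p in inputs.sae_costs.items():
        add(f"sae_cost.{ev}", p)
    for key, p in inputs.utilities.items():
        add(f"utility.{key}", p)
    for key, p in inputs.disutilities.items():
        add(f"disutility.{key}", p)
    for strat, p in inputs.subsequent_tx_share.items():
        add(f"share.{strat}", p, "beta")
    if include_discount:
        specs.append(ParamSpec("discount_rate", discount_rate,
                               discount_range[0], discount_range[1], "fixed"))
    return specs


def apply_overrides(inputs: EconomicInputs, overrides: dict[str, float]) -> EconomicInputs:
    """Return a copy of the inputs with named parameters replaced.

    Sampled values may legitimately fall outside the printed deterministic
    range, so the range is dropped on overridden entries.
    """
    out = inputs.copy()
    for name, value in overrides.items():
        if name == "discount_rate":
            continue  # handled by the evaluator
        group, _, key = name.partition(".")
        value = float(value)
        if group == "price":
            out.drug_prices[key].price = Param(value, dist=out.drug_prices[key].price.dist)
        elif group == "cost":
            out.unit_costs[key] = Param(value, dist=out.unit_costs[key].dist)
        elif group == "sae_cost":
            out.sae_costs[key] = Param(value, dist=out.sae_costs[key].dist)
        elif group == "utility":
            out.utilities[key] = Param(min(max(value, 0.0), 1.0), dist="beta")
        elif group == "disutility":
            out.disutilities[key] = Param(min(max(value, 0.0), 1.0), dist="beta")
        elif group == "share":
            out.subsequent_tx_share[key] = Param(min(max(value, 0.0), 1.0), dist="beta")
        else:
            raise KeyError(f"unknown parameter {name!r}")
    out.validate()
    return out


class CEAEvaluator:
    """Full-model evaluation at (possibly overridden) economic parameters.

    Survival curves fix the state occupancy, which is computed once; each
    evaluation re-accumulates costs and QALYs (and re-weights discounting when
    the discount rate itself is varied).
    """

    def __init__(
        self,
        survival_models: dict[str, dict[str, ParametricSurvival]],
        inputs: EconomicInputs,
        wtp: float,
        discount_rate: float = 0.05,
        cycle_length_days: float = 21.0,
        time_grid: str = "calendar",
        stop_quantile: float = 0.99,
        max_horizon_months: float = 360.0,
        schedule: DosingSchedule | None = None,
        cost_settings: CostSettings | None = None,
    ):
        self.inputs = inputs
        self.wtp = wtp
        self.discount_rate = discount_rate
        self.schedule = schedule or DosingSchedule()
        self.cost_settings = cost_settings or CostSettings()
        strategies = list(survival_models)
        if len(strategies) != 2:
            raise ValueError("expected exactly two strategies")
        self.intervention, self.comparator = strategies
        self.grid = build_grid([m["os"] for m in survival_models.values()],
                               stop_quantile=stop_quantile,
                               cycle_length_days=cycle_length_days,
                               time_grid=time_grid,
                               max_horizon_months=max_horizon_months)
        self.traces = {
            strat: state_occupancy(m["os"], m["pfs"], self.grid, discount_rate)
            for strat, m in survival_models.items()
        }

    def run(self, overrides: dict[str, float] | None = None) -> CEAResult:
        overrides = overrides or {}
        inputs = apply_overrides(self.inputs, overrides) if overrides else self.inputs
        rate = float(overrides.get("discount_rate", self.discount_rate))
        results = []
        for strat in (self.intervention, self.comparator):
            trace = self.traces[strat]
            if rate != trace.discount_rate:
                trace = trace.with_discount_rate(rate)
            cost = accumulate_costs(trace, inputs, strat, self.schedule, self.cost_settings)
            qaly = accumulate_qalys(trace, inputs, strat)
            ly = expected_time(trace, "alive") / 12.0
            results.append(StrategyResult(strat, cost, qaly, ly))
        return CEAResult(results[0], results[1], self.wtp)


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    base: float
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    flagged: bool = False

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def owsa(evaluator: CEAEvaluator, specs: list[ParamSpec]) -> list[TornadoEntry]:
    """One-way sensitivity analysis; entries sorted by ICER swing, descending."""
    entries = []
    for spec in specs:
        icers = []
        flagged = False
        for value in (spec.low, spec.high):
            try:
                res = evaluator.run({spec.name: value})
                icer = res.icer
                if not np.isfinite(icer):
                    flagged = True
            except Exception as exc:  # keep the entry, mark it
                warnings.warn(f"OWSA failure for {spec.name}={value}: {exc}")
                icer, flagged = float("nan"), True
            icers.append(icer)
        entries.append(TornadoEntry(spec.name, spec.base, spec.low, spec.high,
                                    icers[0], icers[1], flagged))
    return sorted(entries, key=lambda e: (np.isnan(e.swing), -e.swing if not np.isnan(e.swing) else 0.0))


def _moments(spec: ParamSpec) -> tuple[float, float]:
    sd = (spec.high - spec.low) / (2.0 * 1.96)
    return spec.base, sd


def _sample_one(spec: ParamSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    mean, sd = _moments(spec)
    if spec.dist == "fixed" or sd <= 0 or mean == 0:
        return np.full(n, spec.base)
    if spec.dist == "gamma":
        if mean <= 0:
            raise ValueError(f"{spec.name}: gamma requires a positive base")
        shape = (mean / sd) ** 2
        return rng.gamma(shape, mean / shape, size=n)
    if spec.dist == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"{spec.name}: beta requires a base strictly in (0, 1)")
        sd = min(sd, 0.99 * np.sqrt(mean * (1 - mean)))  # keep moments feasible
        nu = mean * (1 - mean) / sd ** 2 - 1.0
        return rng.beta(mean * nu, (1 - mean) * nu, size=n)
    raise ValueError(f"{spec.name}: unknown distribution {spec.dist!r}")


def sample_matrix(specs: list[ParamSpec], seed: int, n_iter: int) -> dict[str, np.ndarray]:
    """n_iter joint draws; one spawned substream per parameter."""
    children = np.random.SeedSequence(seed).spawn(len(specs))
    return {spec.name: _sample_one(spec, np.random.default_rng(child), n_iter)
            for spec, child in zip(specs, children)}


def sample_params(specs: list[ParamSpec], seed: int) -> dict[str, float]:
    """A single joint parameter draw (reproducible given the seed)."""
    return {name: float(v[0]) for name, v in sample_matrix(specs, seed, 1).items()}


@dataclass
class PSAResult:
    """Monte-Carlo iterations of (incremental cost, incremental QALY)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_iter: int
    seed: int
    failures: list[int]

    @property
    def iterations(self) -> np.ndarray:
        return np.column_stack([self.delta_cost, self.delta_qaly])


def run_psa(
    evaluator: CEAEvaluator,
    specs: list[ParamSpec],
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Joint Monte-Carlo re-evaluation of the full model.

    The discount rate is treated as fixed in the probabilistic analysis (its
    tag in the input table); any iteration that fails is recorded by index and
    the run continues.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    draws = sample_matrix(specs, seed, n_iter)
    dc = np.full(n_iter, np.nan)
    dq = np.full(n_iter, np.nan)
    failures: list[int] = []
    for i in range(n_iter):
        overrides = {name: float(v[i]) for name, v in draws.items()}
        try:
            res = evaluator.run(overrides)
        except Exception as exc:
            warnings.warn(f"PSA iteration {i} failed: {exc}")
            failures.append(i)
            continue
        dc[i] = res.incremental_cost
        dq[i] = res.incremental_qaly
    return PSAResult(dc, dq, n_iter, seed, failures)


def ceac(psa: PSAResult, wtp_grid) -> dict[float, float]:
    """Probability of positive net monetary benefit at each threshold.

    Iterations with NMB exactly zero count as not cost-effective.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    ok = ~np.isnan(psa.delta_cost)
    dc, dq = psa.delta_cost[ok], psa.delta_qaly[ok]
    if dc.size == 0:
        raise ValueError("no successful PSA iterations")
    return {float(w): float(np.mean(w * dq - dc > 0.0)) for w in wtp_grid}


def ceac_crossing(psa: PSAResult, wtp_grid, probability: float = 0.5) -> float:
    """Smallest grid threshold whose acceptability first reaches ``probability``."""
    curve = ceac(psa, wtp_grid)
    for w in sorted(curve):
        if curve[w] >= probability:
            return w
    return float("nan")
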