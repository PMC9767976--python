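"""Synthetic study-data generation for end-to-end testing without trial data.

Emulates the inputs the analysis consumes: right-censored event times drawn
from a known parametric truth (administrative cutoff plus independent
exponential dropout, i.e. non-informative censoring), digitizer-style
(time, survival) coordinates with a numbers-at-risk table sampled from the
Kaplan-Meier estimate, and complete economic-input sets with the same
(value, low, high, distribution) structure as the base-case table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

from .economics import EconomicInputs, Param
from .fixtures import economics_from_dict, economics_to_dict, orient15_economics
from .survival import DigitizedCurve, ParametricSurvival, PseudoIPD

__all__ = ["SimScenario", "gen_ipd", "gen_digitized_curve", "gen_economic_fixture"]


@dataclass
class SimScenario:
    """Truth models per arm/endpoint plus the observation process."""

    truth: dict[str, dict[str, ParametricSurvival]]  # arm -> endpoint -> model
    n_per_arm: int = 300
    cutoff_months: float = 36.0          # administrative censoring
    dropout_rate_per_month: float = 0.0  # independent exponential dropout
    grid_points: int = 30                # digitization grid
    round_decimals: int | None = 3       # digitizer resolution (rounding only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 10:
            raise ValueError("sample size must be at least 10")
        if self.cutoff_months <= 0:
            raise ValueError("cutoff must be positive")
        if self.dropout_rate_per_month < 0:
            raise ValueError("dropout rate must be non-negative")


def _rng(scenario: SimScenario, arm: str, endpoint: str) -> np.random.Generator:
    # stable per-(arm, endpoint) substream of the scenario seed
    tag = zlib.crc32(f"{arm}/{endpoint}".encode())
    return np.random.default_rng([scenario.seed, tag])


def gen_ipd(scenario: SimScenario, arm: str, endpoint: str) -> PseudoIPD:
    """Censored sample from the truth model of one arm/endpoint."""
    model = scenario.truth[arm][endpoint]
    rng = _rng(scenario, arm, endpoint)
    event_times = model.rvs(scenario.n_per_arm, rng)
    if scenario.dropout_rate_per_month > 0:
        dropout = rng.exponential(1.0 / scenario.dropout_rate_per_month,
                                  size=scenario.n_per_arm)
    else:
        dropout = np.full(scenario.n_per_arm, np.inf)
    censor_at = np.minimum(dropout, scenario.cutoff_months)
    observed = np.minimum(event_times, censor_at)
    events = (event_times <= censor_at).astype(int)
    return PseudoIPD(observed, events)


def gen_digitized_curve(data: PseudoIPD, grid_points: int = 30,
                        round_decimals: int | None = 3) -> DigitizedCurve:
    """Digitizer-style curve: the KM estimate sampled on a uniform time grid.

    Survival values are rounded to the digitizer resolution (no additive
    noise); the numbers at risk at the grid times are included.
    """
    if grid_points < 5:
        raise ValueError("need at least 5 grid points")
    kmf = KaplanMeierFitter().fit(data.times, data.events)
    t_max = float(np.max(data.times))
    grid = np.linspace(t_max / grid_points, t_max, grid_points)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    if round_decimals is not None:
        surv = np.round(surv, round_decimals)
    n_risk = np.array([(data.times >= t).sum() for t in grid], dtype=float)
    return DigitizedCurve(grid, surv, n_risk)


def gen_economic_fixture(seed: int) -> EconomicInputs:
    """A complete, internally consistent random economic-input set.

    Starts from the base-case table and jitters every value (log-normal
    multiplicative noise for prices and costs, logit-scale noise for utilities
    and probabilities), rebuilding the ranges around the new values so all
    schema invariants hold by construction.
    """
    rng = np.random.default_rng(seed)
    base = orient15_economics()
    d = economics_to_dict(base)

    def jitter_cost(p: dict) -> dict:
        v = float(p["value"]) * rng.lognormal(0.0, 0.15)
        return {"value": v, "low": 0.8 * v, "high": 1.2 * v, "dist": p.get("dist", "gamma")}

    def jitter_prob(x: float, lo: float = 0.01, hi: float = 0.99) -> float:
        x = np.clip(x, lo, hi)
        logit = np.log(x / (1 - x)) + rng.normal(0.0, 0.2)
        return float(np.clip(1 / (1 + np.exp(-logit)), lo, hi))

    for drug in d["drug_prices"].values():
        drug["price"] = jitter_cost(drug["price"])
    for key in list(d["unit_costs"]):
        d["unit_costs"][key] = jitter_cost(d["unit_costs"][key])
    for key in list(d["sae_costs"]):
        d["sae_costs"][key] = jitter_cost(d["sae_costs"][key])
    for key in list(d["utilities"]):
        v = jitter_prob(d["utilities"][key]["value"])
        d["utilities"][key] = {"value": v, "low": max(0.0, 0.8 * v),
                               "high": min(1.0, 1.2 * v), "dist": "beta"}
    for key in list(d["disutilities"]):
        v = jitter_prob(d["disutilities"][key]["value"])
        d["disutilities"][key] = {"value": v, "low": max(0.0, 0.8 * v),
                                  "high": min(1.0, 1.2 * v), "dist": "beta"}
    for strat in list(d["subsequent_tx_share"]):
        v = jitter_prob(d["subsequent_tx_share"][strat]["value"])
        d["subsequent_tx_share"][strat] = {"value": v, "dist": "beta"}
    ae = {
        "sae_incidence": {s: {ev: jitter_prob(p) for ev, p in evs.items()}
                          for s, evs in d.pop("sae_incidence").items()},
        "ae_incidence_g12": {s: jitter_prob(p) for s, p in d.pop("ae_incidence_g12").items()},
        "ae_incidence_g34": {s: jitter_prob(p) for s, p in d.pop("ae_incidence_g34").items()},
    }
    return economics_from_dict(d, ae)
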