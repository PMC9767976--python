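"""Cost and QALY accumulation over a partitioned-survival trace, and ICERs.

Costing follows the payer-perspective structure of the analysis this package
reproduces: per-cycle first-line drug + administration costs accrue against
PFS occupancy (treatment until progression), routine follow-up / laboratory /
imaging costs against alive occupancy, best supportive care plus (for a share
of patients) subsequent docetaxel against progressed-disease occupancy, and a
one-off incidence-weighted serious-adverse-event cost in the first cycle.
Utilities weight person-time per state; grade 1-2 and grade 3-4 adverse-event
disutilities are charged once, in the first cycle.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .psm import StateTrace

__all__ = [
    "Param",
    "DrugPrice",
    "DosingSchedule",
    "CostSettings",
    "EconomicInputs",
    "StrategyResult",
    "CEAResult",
    "STRATEGIES",
    "cycle_drug_cost",
    "cost_breakdown",
    "accumulate_costs",
    "accumulate_qalys",
    "compare",
    "wtp_from_gdp",
]

STRATEGIES = ("sintilimab_chemo", "chemo")


@dataclass
class Param:
    """A model input with its deterministic range and PSA distribution tag."""

    value: float
    low: float | None = None
    high: float | None = None
    dist: str = "fixed"  # gamma | beta | fixed

    def __post_init__(self) -> None:
        if self.dist not in ("gamma", "beta", "fixed"):
            raise ValueError(f"unknown distribution tag {self.dist!r}")
        if self.low is not None and self.high is not None:
            if not self.low <= self.value <= self.high:
                raise ValueError(f"range [{self.low}, {self.high}] must bracket {self.value}")
        if self.dist == "beta" and not 0.0 <= self.value <= 1.0:
            raise ValueError("beta-distributed parameters must lie in [0, 1]")

    def bounds(self, default_rel: float = 0.20) -> tuple[float, float]:
        """Deterministic range; +/-20 % of base where no range is given."""
        lo = self.low if self.low is not None else self.value * (1 - default_rel)
        hi = self.high if self.high is not None else self.value * (1 + default_rel)
        return lo, hi


@dataclass
class DrugPrice:
    price: Param          # US$ per pack
    pack_mg: float        # milligrams per pack

    def per_mg(self) -> float:
        return self.price.value / self.pack_mg


@dataclass
class DosingSchedule:
    """Per-3-week-cycle dosing and the reference patient used to fix doses."""

    bsa_m2: float = 1.72
    weight_kg: float = 65.0
    height_m: float = 1.64
    sintilimab_mg_flat: float = 200.0
    cisplatin_mg_per_m2: float = 75.0
    paclitaxel_mg_per_m2: float = 175.0          # 87.5 x 2 in cycle 1, same total
    fluorouracil_mg_per_m2_per_day: float = 800.0
    fluorouracil_days: int = 5
    docetaxel_mg_per_m2: float = 75.0

    def doses_mg(self, regimen: str, cycle_index: int = 2) -> dict[str, float]:
        """Milligrams per drug for one cycle of a regimen."""
        if regimen == "none":
            return {}
        if regimen == "docetaxel":
            return {"docetaxel": self.docetaxel_mg_per_m2 * self.bsa_m2}
        if regimen not in ("sintilimab_chemo", "chemo",
                           "sintilimab_chemo_5fu", "chemo_5fu"):
            raise KeyError(f"unknown regimen {regimen!r}")
        doses: dict[str, float] = {}
        if regimen.startswith("sintilimab"):
            doses["sintilimab"] = self.sintilimab_mg_flat
        doses["cisplatin"] = self.cisplatin_mg_per_m2 * self.bsa_m2
        if regimen.endswith("_5fu"):
            doses["fluorouracil"] = (self.fluorouracil_mg_per_m2_per_day
                                     * self.fluorouracil_days * self.bsa_m2)
        else:
            # day 1 + day 8 split in cycle 1 totals the same milligrams
            doses["paclitaxel"] = self.paclitaxel_mg_per_m2 * self.bsa_m2
        return doses


@dataclass
class CostSettings:
    """Costing frequencies and conventions (documented defaults)."""

    rounding: str = "linear"            # linear per-mg | whole_pack (wastage)
    imaging_every_cycles: int = 2       # chest + abdominal CT every ~6 weeks
    hospitalization_days: int | None = None  # None: 1/cycle, 5 for 5-FU regimens
    max_subsequent_cycles: int = 6      # docetaxel cycles per progressed patient
    max_treatment_cycles: int | None = None  # first-line cap; None = to progression

    def __post_init__(self) -> None:
        if self.rounding not in ("linear", "whole_pack"):
            raise ValueError("rounding must be 'linear' or 'whole_pack'")


@dataclass
class EconomicInputs:
    """Unit prices, routine-care costs, AE inputs and utilities (with ranges)."""

    drug_prices: dict[str, DrugPrice]
    unit_costs: dict[str, Param]          # bsc_per_cycle, followup, ct_chest, ...
    sae_costs: dict[str, Param]
    sae_incidence: dict[str, dict[str, float]]      # strategy -> event -> prob
    subsequent_tx_share: dict[str, Param]           # strategy -> share
    utilities: dict[str, Param]           # pfs, pd
    disutilities: dict[str, Param]        # g12, g34
    ae_incidence_g12: dict[str, float]
    ae_incidence_g34: dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, dp in self.drug_prices.items():
            if dp.price.value < 0 or dp.pack_mg <= 0:
                raise ValueError(f"invalid price entry for {name}")
        for name, p in {**self.unit_costs, **self.sae_costs}.items():
            if p.value < 0:
                raise ValueError(f"cost {name} must be non-negative")
        for name, p in {**self.utilities, **self.disutilities}.items():
            if not 0.0 <= p.value <= 1.0:
                raise ValueError(f"utility input {name} must lie in [0, 1]")
        for strat, share in self.subsequent_tx_share.items():
            if not 0.0 <= share.value <= 1.0:
                raise ValueError(f"subsequent-treatment share for {strat} outside [0, 1]")
        for table in (self.sae_incidence, ):
            for strat, d in table.items():
                for ev, p in d.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"SAE incidence {strat}/{ev} outside [0, 1]")
        for d in (self.ae_incidence_g12, self.ae_incidence_g34):
            for strat, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("AE incidence outside [0, 1]")

    def copy(self) -> "EconomicInputs":
        return copy.deepcopy(self)


def _priced(mg: float, drug: DrugPrice, rounding: str) -> float:
    if rounding == "whole_pack":
        return math.ceil(mg / drug.pack_mg - 1e-9) * drug.price.value
    return mg * drug.per_mg()


def cycle_drug_cost(
    schedule: DosingSchedule,
    regimen: str,
    inputs: EconomicInputs,
    cycle_index: int = 2,
    rounding: str = "linear",
    include_administration: bool = True,
    hospitalization_days: int | None = None,
) -> float:
    """Drug acquisition plus administration cost of one cycle of a regimen.

    Drugs are priced per milligram from the printed pack price (default), or by
    whole packs when vial wastage is assumed.  Administration adds the
    dispensing fee, the intravenous-infusion fee and hospitalization days
    (1 day per cycle; 5 for continuous-infusion 5-FU regimens).
    """
    doses = schedule.doses_mg(regimen, cycle_index)
    cost = 0.0
    for drug, mg in doses.items():
        if drug not in inputs.drug_prices:
            raise KeyError(f"no price for drug {drug!r}")
        cost += _priced(mg, inputs.drug_prices[drug], rounding)
    if include_administration:
        days = hospitalization_days
        if days is None:
            days = 5 if "fluorouracil" in doses else (0 if not doses else 1)
        cost += (inputs.unit_costs["dispensing_fee"].value
                 + inputs.unit_costs["iv_fee"].value
                 + days * inputs.unit_costs["hospitalization_per_day"].value)
    return cost


def weighted_sae_cost(inputs: EconomicInputs, strategy: str) -> float:
    """Incidence-weighted one-off cost of grade >=3 adverse events."""
    if inputs.sae_costs and strategy not in inputs.sae_incidence:
        raise KeyError(f"SAE costs given but no incidence profile for {strategy!r}")
    inc = inputs.sae_incidence.get(strategy, {})
    missing = set(inputs.sae_costs) - set(inc)
    if missing:
        raise KeyError(f"missing SAE incidence for {sorted(missing)}")
    return sum(inc[ev] * p.value for ev, p in inputs.sae_costs.items())


def cost_breakdown(
    trace: StateTrace,
    inputs: EconomicInputs,
    strategy: str,
    schedule: DosingSchedule | None = None,
    settings: CostSettings | None = None,
) -> dict[str, float]:
    """Discounted cost components for one strategy over a trace."""
    if strategy not in STRATEGIES:
        raise KeyError(f"strategy must be one of {STRATEGIES}")
    schedule = schedule or DosingSchedule()
    settings = settings or CostSettings()
    w = trace.discount
    pfs, pd_, alive = trace.pfs, trace.pd, trace.alive
    n = trace.grid.n_cycles
    idx = np.arange(1, n + 1)

    # first-line treatment while progression-free
    per_cycle_drug = cycle_drug_cost(schedule, strategy, inputs,
                                     rounding=settings.rounding,
                                     hospitalization_days=settings.hospitalization_days)
    on_treatment = pfs.copy()
    if settings.max_treatment_cycles is not None:
        on_treatment[idx > settings.max_treatment_cycles] = 0.0
    first_line = float(np.sum(on_treatment * w)) * per_cycle_drug

    # routine care while alive
    routine_per_cycle = inputs.unit_costs["followup"].value + inputs.unit_costs["lab"].value
    routine = float(np.sum(alive * w)) * routine_per_cycle
    imaging_cost = inputs.unit_costs["ct_chest"].value + inputs.unit_costs["ct_abdomen"].value
    imaging_cycles = (idx - 1) % settings.imaging_every_cycles == 0
    imaging = float(np.sum(alive[imaging_cycles] * w[imaging_cycles])) * imaging_cost

    # progressed disease: best supportive care, plus subsequent docetaxel for a
    # share of patients during their first max_subsequent_cycles cycles of PD
    bsc = float(np.sum(pd_ * w)) * inputs.unit_costs["bsc_per_cycle"].value
    k = settings.max_subsequent_cycles
    pfs_shifted = np.ones_like(pfs)
    if k < n:
        pfs_shifted[k:] = pfs[:-k]
    recent_pd = np.minimum(np.clip(pfs_shifted - pfs, 0.0, None), pd_)
    doc_cycle = cycle_drug_cost(schedule, "docetaxel", inputs, rounding=settings.rounding)
    share = inputs.subsequent_tx_share[strategy].value
    subsequent = float(np.sum(recent_pd * w)) * doc_cycle * share

    sae = weighted_sae_cost(inputs, strategy) * float(w[0])

    return {
        "first_line": first_line,
        "routine": routine,
        "imaging": imaging,
        "bsc": bsc,
        "subsequent_treatment": subsequent,
        "sae": sae,
    }


def accumulate_costs(
    trace: StateTrace,
    inputs: EconomicInputs,
    strategy: str,
    schedule: DosingSchedule | None = None,
    settings: CostSettings | None = None,
) -> float:
    """Total discounted cost of one strategy (US$)."""
    return float(sum(cost_breakdown(trace, inputs, strategy, schedule, settings).values()))


def accumulate_qalys(trace: StateTrace, inputs: EconomicInputs, strategy: str) -> float:
    """Discounted quality-adjusted life-years of one strategy.

    Per-cycle utility-weighted person-time (u_pfs in PFS, u_pd in PD), minus
    incidence-weighted adverse-event disutilities charged in the first cycle.
    """
    u_pfs = inputs.utilities["pfs"].value
    u_pd = inputs.utilities["pd"].value
    for u in (u_pfs, u_pd):
        if not 0.0 <= u <= 1.0:
            raise ValueError("utilities must lie in [0, 1]")
    dt = trace.dt_years
    q = float(np.sum((trace.pfs * u_pfs + trace.pd * u_pd) * trace.discount)) * dt
    disutil = (inputs.ae_incidence_g12.get(strategy, 0.0) * inputs.disutilities["g12"].value
               + inputs.ae_incidence_g34.get(strategy, 0.0) * inputs.disutilities["g34"].value)
    q -= disutil * dt * float(trace.discount[0])
    return q


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    cost: float
    qaly: float
    life_years: float = float("nan")


@dataclass(frozen=True)
class CEAResult:
    """Comparative result: incrementals, ICER, dominance and NMB verdict."""

    intervention: StrategyResult
    comparator: StrategyResult
    wtp: float
    incremental_cost: float = field(init=False)
    incremental_qaly: float = field(init=False)
    icer: float = field(init=False)
    dominance: str | None = field(init=False)
    cost_effective: bool = field(init=False)

    def __post_init__(self) -> None:
        dc = self.intervention.cost - self.comparator.cost
        dq = self.intervention.qaly - self.comparator.qaly
        object.__setattr__(self, "incremental_cost", dc)
        object.__setattr__(self, "incremental_qaly", dq)
        dominance = None
        icer = float("nan")
        if dq > 0 and dc <= 0:
            dominance = "intervention_dominant"
        elif dq < 0 and dc >= 0:
            dominance = "intervention_dominated"
        elif dq == 0:
            dominance = "equivalent_effect"
        else:
            icer = dc / dq
        object.__setattr__(self, "icer", icer)
        object.__setattr__(self, "dominance", dominance)
        # ties (NMB exactly 0) count as not cost-effective
        nmb = self.wtp * dq - dc
        object.__setattr__(self, "cost_effective", bool(nmb > 0))

    def nmb(self, strategy_result: StrategyResult) -> float:
        return self.wtp * strategy_result.qaly - strategy_result.cost


def compare(results, wtp: float) -> CEAResult:
    """ICER of the first (intervention) vs second (comparator) strategy."""
    if len(results) != 2:
        raise ValueError("compare expects exactly two strategies (intervention, comparator)")
    out = []
    for r in results:
        if isinstance(r, StrategyResult):
            out.append(r)
        else:
            out.append(StrategyResult(*r))
    return CEAResult(out[0], out[1], wtp)


def wtp_from_gdp(per_capita_gdp: float, multiplier: float = 3.0) -> float:
    """Willingness-to-pay threshold as a multiple of per-capita GDP."""
    return multiplier * per_capita_gdp
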