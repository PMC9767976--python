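"""Loading and serialization of model inputs (YAML dialect).

The packaged ``orient15.yaml`` transcribes the published base case: fitted
survival parameters per population/arm/endpoint and the cost/utility table
with deterministic ranges and PSA distribution tags.  Adverse-event
incidences, which the source does not reprint, ship separately as a clearly
labelled synthetic profile (``ae_profile_synthetic.yaml``).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .economics import DrugPrice, EconomicInputs, Param
from .survival import ParametricSurvival

__all__ = [
    "POPULATIONS",
    "load_fixture",
    "orient15_survival",
    "orient15_economics",
    "orient15_settings",
    "economics_to_dict",
    "economics_from_dict",
]

POPULATIONS = ("overall", "cps_ge_10")


def _read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _packaged(name: str) -> dict:
    with resources.files("psmcea.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _param(d) -> Param:
    if isinstance(d, (int, float)):
        return Param(float(d))
    return Param(float(d["value"]), d.get("low"), d.get("high"), d.get("dist", "fixed"))


def _model(d) -> ParametricSurvival:
    return ParametricSurvival(d["family"], float(d["location"]),
                              float(d.get("scale", 1.0)), d.get("extra"))


def economics_from_dict(econ: dict, ae_profile: dict) -> EconomicInputs:
    return EconomicInputs(
        drug_prices={k: DrugPrice(_param(v["price"]), float(v["pack_mg"]))
                     for k, v in econ["drug_prices"].items()},
        unit_costs={k: _param(v) for k, v in econ["unit_costs"].items()},
        sae_costs={k: _param(v) for k, v in econ["sae_costs"].items()},
        sae_incidence={s: dict(v) for s, v in ae_profile["sae_incidence"].items()},
        subsequent_tx_share={k: _param(v) for k, v in econ["subsequent_tx_share"].items()},
        utilities={k: _param(v) for k, v in econ["utilities"].items()},
        disutilities={k: _param(v) for k, v in econ["disutilities"].items()},
        ae_incidence_g12=dict(ae_profile["ae_incidence_g12"]),
        ae_incidence_g34=dict(ae_profile["ae_incidence_g34"]),
    )


def _param_dict(p: Param) -> dict:
    d = {"value": p.value, "dist": p.dist}
    if p.low is not None:
        d["low"] = p.low
    if p.high is not None:
        d["high"] = p.high
    return d


def economics_to_dict(inputs: EconomicInputs) -> dict:
    return {
        "drug_prices": {k: {"price": _param_dict(v.price), "pack_mg": v.pack_mg}
                        for k, v in inputs.drug_prices.items()},
        "unit_costs": {k: _param_dict(v) for k, v in inputs.unit_costs.items()},
        "sae_costs": {k: _param_dict(v) for k, v in inputs.sae_costs.items()},
        "subsequent_tx_share": {k: _param_dict(v)
                                for k, v in inputs.subsequent_tx_share.items()},
        "utilities": {k: _param_dict(v) for k, v in inputs.utilities.items()},
        "disutilities": {k: _param_dict(v) for k, v in inputs.disutilities.items()},
        "sae_incidence": {s: dict(v) for s, v in inputs.sae_incidence.items()},
        "ae_incidence_g12": dict(inputs.ae_incidence_g12),
        "ae_incidence_g34": dict(inputs.ae_incidence_g34),
    }


def load_fixture(path: str | Path | None = None) -> dict:
    """Raw fixture dictionary (packaged base case unless a path is given)."""
    return _read_yaml(path) if path else _packaged("orient15.yaml")


def orient15_survival(population: str = "overall",
                      path: str | Path | None = None
                      ) -> dict[str, dict[str, ParametricSurvival]]:
    """Fitted survival models keyed strategy -> endpoint for one population."""
    fx = load_fixture(path)
    if population not in fx["survival"]:
        raise KeyError(f"unknown population {population!r}; "
                       f"expected one of {sorted(fx['survival'])}")
    return {strat: {ep: _model(d) for ep, d in arms.items()}
            for strat, arms in fx["survival"][population].items()}


def orient15_economics(path: str | Path | None = None,
                       ae_profile_path: str | Path | None = None) -> EconomicInputs:
    """Economic inputs; AE incidences default to the synthetic shipped profile."""
    fx = load_fixture(path)
    ae = _read_yaml(ae_profile_path) if ae_profile_path else _packaged("ae_profile_synthetic.yaml")
    return economics_from_dict(fx["economics"], ae)


def orient15_settings(path: str | Path | None = None) -> dict:
    fx = load_fixture(path)
    out = dict(fx["settings"])
    out["wtp_per_qaly"] = float(fx["wtp_per_qaly"])
    out["per_capita_gdp"] = float(fx["per_capita_gdp"])
    return out
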