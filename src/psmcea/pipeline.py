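"""Run configuration, orchestration and bit-stable result export.

A run reproduces the full analysis for one population: survival inputs (either
the published fitted parameters or a refit from digitized curves), the
partitioned-survival trace, cost/QALY accumulation and comparison, and the
optional one-way and probabilistic sensitivity analyses.  All outputs are CSV
files with a versioned schema header plus a JSON manifest recording the
resolved configuration hash, seed and package version; two runs with the same
configuration produce byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .economics import CostSettings, DosingSchedule, STRATEGIES
from .fixtures import (POPULATIONS, load_fixture, orient15_economics,
                       orient15_settings, orient15_survival)
from .sensitivity import (CEAEvaluator, build_param_specs, ceac, ceac_crossing,
                          owsa, run_psa)
from .survival import (DigitizedCurve, FAMILIES, fit_all, fit_report,
                       reconstruct_ipd, select_best)

__all__ = ["ConfigError", "RunConfig", "load_config", "run_pipeline",
           "write_csv", "read_csv"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class PSAConfig:
    enabled: bool = False
    n_iter: int = 1000
    seed: int | None = None
    wtp_grid_start: float = 0.0
    wtp_grid_stop: float = 50000.0
    wtp_grid_step: float = 500.0


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    population: str = "overall"
    survival_source: str = "table3_parameters"   # or refit_from_curves
    curves: dict | None = None       # strategy -> endpoint -> CSV path
    n_start: int = 300               # cohort size for pseudo-IPD reconstruction
    selection_criterion: str = "aic"
    fixture_path: str | None = None
    ae_profile_path: str | None = None
    cycle_length_days: float = 21.0
    discount_rate: float = 0.05
    stop_quantile: float = 0.99
    time_grid: str = "reference"
    max_horizon_months: float = 360.0
    wtp_per_qaly: float = 37654.50
    discount_life_years: bool = True
    imaging_every_cycles: int = 2
    max_subsequent_cycles: int = 6
    rounding: str = "linear"
    owsa: bool = True
    psa: PSAConfig = field(default_factory=PSAConfig)
    out_dir: str = "results"
    defaulted_fields: list = field(default_factory=list, repr=False)

    def validate(self) -> None:
        if self.population not in POPULATIONS:
            raise ConfigError(f"population must be one of {POPULATIONS}")
        if self.survival_source not in ("table3_parameters", "refit_from_curves"):
            raise ConfigError("survival source must be 'table3_parameters' or "
                              "'refit_from_curves'")
        if self.survival_source == "refit_from_curves":
            if not self.curves:
                raise ConfigError("refit_from_curves requires 'curves' paths")
            for strat, eps in self.curves.items():
                if strat not in STRATEGIES:
                    raise ConfigError(f"unknown strategy {strat!r} in curves")
                for ep, p in eps.items():
                    if ep not in ("os", "pfs"):
                        raise ConfigError(f"curve endpoint must be os/pfs, got {ep!r}")
                    if not Path(p).exists():
                        raise ConfigError(f"curve file not found: {p}")
        for name in ("fixture_path", "ae_profile_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} not found: {p}")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ConfigError("discount rate must lie in [0, 1]")
        if not 0.0 < self.stop_quantile < 1.0:
            raise ConfigError("stop quantile must lie in (0, 1)")
        if self.cycle_length_days <= 0:
            raise ConfigError("cycle length must be positive")
        if self.time_grid not in ("calendar", "reference"):
            raise ConfigError("time_grid must be 'calendar' or 'reference'")
        if self.psa.enabled and self.psa.seed is None:
            raise ConfigError("a seed is required when the PSA is enabled")
        if self.psa.enabled and self.psa.n_iter < 1:
            raise ConfigError("psa n_iter must be at least 1")

    def resolved_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("defaulted_fields", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)} - {"defaulted_fields"}
_PSA_KEYS = {f.name for f in dataclasses.fields(PSAConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling documented defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    psa_raw = raw.pop("psa", None) or {}
    unknown_psa = set(psa_raw) - _PSA_KEYS
    if unknown_psa:
        raise ConfigError(f"unknown psa key(s): {sorted(unknown_psa)}")
    cfg = RunConfig(**raw, psa=PSAConfig(**psa_raw))
    cfg.defaulted_fields = sorted(_KNOWN_KEYS - set(raw) - {"psa"})
    try:
        cfg.validate()
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.resolved_dict()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# schema-versioned CSV export
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path: Path, schema: str) -> None:
    """CSV with a one-line schema header; floats at full reproducible precision."""
    header = (f"# psmcea-schema: {schema}/v{SCHEMA_VERSION} "
              f"columns={','.join(df.columns)}\n")
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_csv(path: Path, schema: str | None = None) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# psmcea-schema:"):
            raise ValueError(f"{path} lacks a psmcea schema header")
        if schema is not None and f" {schema}/v" not in first:
            raise ValueError(f"{path} is not schema {schema!r}: {first.strip()}")
        df = pd.read_csv(fh)
    declared = first.rsplit("columns=", 1)[1].strip().split(",")
    if list(df.columns) != declared:
        raise ValueError(f"{path}: columns {list(df.columns)} != declared {declared}")
    return df


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _survival_models(cfg: RunConfig):
    """(models, fit_tables): published parameters or a refit from curves."""
    if cfg.survival_source == "table3_parameters":
        return orient15_survival(cfg.population, cfg.fixture_path), {}
    models: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    base = orient15_survival(cfg.population, cfg.fixture_path)
    for strat in STRATEGIES:
        models[strat] = dict(base[strat])
        for ep, path in (cfg.curves.get(strat) or {}).items():
            curve = DigitizedCurve.from_csv(path)
            ipd = reconstruct_ipd(curve, cfg.n_start)
            fits = fit_all(ipd)
            best = select_best(fits, cfg.selection_criterion)
            models[strat][ep] = best.model
            tables[f"{strat}_{ep}"] = fit_report(fits)
    return models, tables


def run_pipeline(cfg: RunConfig, quiet: bool = False):
    """Execute fit -> trace -> economics -> sensitivity, exporting as it goes.

    Any stage failure is recorded in the manifest (with the stage name) and
    the partial outputs written so far are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "psmcea",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.resolved_dict(),
        "defaulted_fields": cfg.defaulted_fields,
        "seed": cfg.psa.seed,
        "stages": {},
        "notes": [],
    }
    captured: list[str] = []
    results = {}
    settings = CostSettings(rounding=cfg.rounding,
                            imaging_every_cycles=cfg.imaging_every_cycles,
                            max_subsequent_cycles=cfg.max_subsequent_cycles)
    try:
        stage = "fit"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            models, fit_tables = _survival_models(cfg)
            for name, table in fit_tables.items():
                write_csv(table, out / f"fit_report_{name}.csv", "fit_report")
            manifest["stages"]["fit"] = "ok"

            stage = "trace"
            inputs = orient15_economics(cfg.fixture_path, cfg.ae_profile_path)
            evaluator = CEAEvaluator(
                models, inputs, cfg.wtp_per_qaly,
                discount_rate=cfg.discount_rate,
                cycle_length_days=cfg.cycle_length_days,
                time_grid=cfg.time_grid,
                stop_quantile=cfg.stop_quantile,
                max_horizon_months=cfg.max_horizon_months,
                cost_settings=settings,
            )
            for strat, trace in evaluator.traces.items():
                write_csv(trace.to_frame(), out / f"trace_{strat}.csv", "trace")
            manifest["notes"].append(
                {"time_grid": cfg.time_grid,
                 "n_cycles": evaluator.grid.n_cycles,
                 "horizon_months": evaluator.grid.horizon_months,
                 "horizon_capped": evaluator.grid.capped,
                 "pd_clamped_cycles": {s: t.n_clamped
                                       for s, t in evaluator.traces.items()}})
            manifest["stages"]["trace"] = "ok"

            stage = "economics"
            base = evaluator.run()
            results["base"] = base
            rows = []
            for sr in (base.intervention, base.comparator):
                is_int = sr.strategy == base.intervention.strategy
                rows.append({
                    "strategy": sr.strategy,
                    "total_cost_usd": sr.cost,
                    "life_years": sr.life_years,
                    "qalys": sr.qaly,
                    "incremental_cost_usd": base.incremental_cost if is_int else np.nan,
                    "incremental_qalys": base.incremental_qaly if is_int else np.nan,
                    "icer_usd_per_qaly": base.icer if is_int else np.nan,
                    "nmb_usd": base.nmb(sr),
                })
            write_csv(pd.DataFrame(rows), out / "cea_results.csv", "cea_results")
            manifest["stages"]["economics"] = "ok"

            stage = "owsa"
            specs = build_param_specs(inputs, cfg.discount_rate)
            if cfg.owsa:
                entries = owsa(evaluator, specs)
                df = pd.DataFrame([{
                    "parameter": e.name, "base": e.base, "low": e.low, "high": e.high,
                    "icer_at_low": e.icer_at_low, "icer_at_high": e.icer_at_high,
                    "swing": e.swing, "flagged": e.flagged} for e in entries])
                write_csv(df, out / "tornado.csv", "tornado")
                results["owsa"] = entries
                manifest["stages"]["owsa"] = "ok"
            else:
                manifest["stages"]["owsa"] = "skipped"

            stage = "psa"
            if cfg.psa.enabled:
                psa = run_psa(evaluator, specs, cfg.psa.n_iter, cfg.psa.seed)
                write_csv(pd.DataFrame({"iteration": np.arange(psa.n_iter),
                                        "delta_cost_usd": psa.delta_cost,
                                        "delta_qalys": psa.delta_qaly}),
                          out / "psa_iterations.csv", "psa_iterations")
                grid = np.arange(cfg.psa.wtp_grid_start,
                                 cfg.psa.wtp_grid_stop + cfg.psa.wtp_grid_step,
                                 cfg.psa.wtp_grid_step)
                curve = ceac(psa, grid)
                write_csv(pd.DataFrame({"wtp_usd_per_qaly": list(curve),
                                        "prob_cost_effective": list(curve.values())}),
                          out / "ceac.csv", "ceac")
                results["psa"] = psa
                results["ceac"] = curve
                results["ceac_50pct_wtp"] = ceac_crossing(psa, grid)
                manifest["stages"]["psa"] = "ok"
            else:
                manifest["stages"]["psa"] = "skipped"
        captured = sorted({str(w.message) for w in wlist})
    except Exception as exc:
        manifest["stages"][stage] = "failed"
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest["warnings"] = captured
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    if not quiet:
        base = results["base"]
        print(f"population={cfg.population} time_grid={cfg.time_grid}")
        for sr in (base.intervention, base.comparator):
            print(f"  {sr.strategy}: cost={sr.cost:,.2f} US$  LY={sr.life_years:.2f}  "
                  f"QALY={sr.qaly:.2f}")
        icer = "dominant" if base.dominance else f"{base.icer:,.2f} US$/QALY"
        print(f"  incremental cost={base.incremental_cost:,.2f} US$  "
              f"dQALY={base.incremental_qaly:.2f}  ICER={icer}")
    return results
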