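"""End-to-end orchestration: simulate/load -> clean -> fit -> evaluate -> overlay -> biomass.

A single :class:`PipelineConfig` (usually read from YAML) drives the whole
analysis.  One master seed deterministically spawns per-stage seeds so any
stage can be re-run in isolation and a re-run with the same config and
seed reproduces the report bit for bit (timestamps aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import biomass_monod, enceladus_overlay, model_eval, niche_envelope
from .io_formats import EnvStack, read_env_stack, read_occurrences, \
    write_env_stack, write_occurrences, write_suitability_raster
from .synthetic_data import SimConfig, TrueEnvelope, default_true_envelope, \
    generate_layers, generate_occurrences

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "spawn_seeds"]

_STAGES = ("simulate", "split", "filter", "eval", "occurrences")


def spawn_seeds(master_seed: int) -> dict[str, int]:
    """Derive one deterministic sub-seed per stochastic stage."""
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input source.

    Either ``synthetic`` (a SimConfig-shaped mapping) or both
    ``occurrence_csv`` and ``raster_paths`` must be given, never both.
    """

    synthetic: dict | None = None
    occurrence_csv: str | None = None
    raster_paths: list[str] | None = None
    raster_names: list[str] | None = None
    variables: list[str] | None = None       # None: all retained after filter
    train_frac: float = 0.75
    corr_threshold: float = 0.8
    corr_points: int = 10_000
    trim_percentile: float = 0.0
    E: float = 0.05
    n_boot: int = 1000
    resample_frac: float = 0.5
    scenario: str = "both"                   # full_ocean | hydrothermal | both
    growth_horizon: float = biomass_monod.CONSTANTS["life_horizon"]["value"]
    constants_overrides: dict = field(default_factory=dict)
    conditions_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.occurrence_csv is not None or self.raster_paths is not None
        if self.synthetic is not None and has_files:
            raise ValueError(
                "config must give either a synthetic block or input paths, "
                "not both"
            )
        if self.synthetic is None and not (
            self.occurrence_csv and self.raster_paths
        ):
            raise ValueError(
                "config needs a synthetic block, or occurrence_csv plus "
                "raster_paths"
            )
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0 < self.E < 1:
            raise ValueError("E must lie in (0, 1)")
        if self.scenario not in {"full_ocean", "hydrothermal", "both"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _budget_from_overrides(overrides: dict) -> biomass_monod.HydrogenBudget:
    fields = {k: v for k, v in overrides.items()
              if k in biomass_monod.HydrogenBudget.__dataclass_fields__}
    return biomass_monod.HydrogenBudget(**fields)


def _params_from_overrides(overrides: dict) -> biomass_monod.GrowthParameters:
    fields = {k: v for k, v in overrides.items()
              if k in biomass_monod.GrowthParameters.__dataclass_fields__}
    return biomass_monod.GrowthParameters(**fields)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage and return (and optionally write) the run report."""
    t_start = time.time()
    seeds = spawn_seeds(config.seed)
    report: dict = {"master_seed": config.seed, "stage_seeds": seeds}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.synthetic is not None:
        sim_kwargs = dict(config.synthetic)
        truth_block = sim_kwargs.pop("truth", None)
        n_occ = sim_kwargs.pop("n_occurrences", 200)
        noise = sim_kwargs.pop("noise", 0.0)
        sim_kwargs.setdefault("seed", seeds["simulate"])
        if "shape" in sim_kwargs:
            sim_kwargs["shape"] = tuple(sim_kwargs["shape"])
        if "variables" in sim_kwargs:
            sim_kwargs["variables"] = {
                k: tuple(v) for k, v in sim_kwargs["variables"].items()
            }
        sim = SimConfig(n_occurrences=n_occ, noise=noise, **sim_kwargs)
        stack = generate_layers(sim)
        truth = (
            TrueEnvelope({k: tuple(v) for k, v in truth_block.items()})
            if truth_block else default_true_envelope(stack)
        )
        raw_occ = generate_occurrences(
            stack, truth, n=sim.n_occurrences, noise=sim.noise,
            seed=seeds["occurrences"],
        )
        report["input"] = {
            "mode": "synthetic",
            "grid_shape": list(stack.shape),
            "true_envelope": {k: list(v) for k, v in truth.limits.items()},
            "n_occurrences": len(raw_occ),
        }
        if outdir is not None:
            write_env_stack(stack, outdir / "layers", fmt="asc")
            write_occurrences(raw_occ, outdir / "occurrences.csv")
            with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(report["input"], fh, indent=2)
    else:
        stack = read_env_stack(config.raster_paths, config.raster_names)
        raw_occ = read_occurrences(config.occurrence_csv)
        report["input"] = {
            "mode": "files",
            "occurrence_csv": config.occurrence_csv,
            "rasters": list(config.raster_paths),
            "n_occurrences": len(raw_occ),
        }

    # --- collinearity pre-filter -----------------------------------------
    retained = niche_envelope.correlation_filter(
        stack, n_points=config.corr_points,
        threshold=config.corr_threshold, seed=seeds["filter"],
    )
    if config.variables:
        retained = [v for v in retained if v in config.variables]
    report["retained_variables"] = retained

    # --- clean / split / fit / predict ------------------------------------
    occ = niche_envelope.clean_and_split(
        raw_occ, stack, train_frac=config.train_frac, seed=seeds["split"]
    )
    report["occurrences"] = occ.counts()
    model = niche_envelope.fit_bioclim(
        occ, stack, variables=retained, trim_percentile=config.trim_percentile
    )
    report["envelope"] = {
        v: list(model.limits(v)) for v in model.variables
    }
    suitability = niche_envelope.predict_suitability(model, stack)
    if outdir is not None:
        write_suitability_raster(suitability, stack, outdir / "suitability.asc")
        with open(outdir / "model.json", "w", encoding="utf-8") as fh:
            json.dump(model.to_dict(), fh, indent=2)

    # --- partial ROC -------------------------------------------------------
    test_suit = model_eval.extract_test_suitability(suitability, stack, occ)
    roc = model_eval.partial_roc(
        suitability, test_suit, nodata=stack.nodata, E=config.E,
        n_boot=config.n_boot, resample_frac=config.resample_frac,
        seed=seeds["eval"],
    )
    report["partial_roc"] = roc.to_dict()

    # --- Enceladus overlay -------------------------------------------------
    curves = [niche_envelope.response_curve(model, v) for v in model.variables]
    conditions = [
        c for c in enceladus_overlay.default_enceladus_conditions()
        if c.variable in model.variables
    ]
    for var, bounds in config.conditions_overrides.items():
        conditions = [c for c in conditions if c.variable != var]
        by_var = {c.variable: c for c in curves}
        if var in by_var:
            conditions.append(enceladus_overlay.ConditionInterval(
                var, float(bounds[0]), float(bounds[1]),
                by_var[var].units, "user override",
            ))
    if conditions:
        overlap = enceladus_overlay.overlay(curves, conditions)
        report["overlay"] = overlap.to_dict()
        if outdir is not None:
            with open(outdir / "response_curves.csv", "w", encoding="utf-8") as fh:
                fh.write("variable,value,score\n")
                for c in curves:
                    for x, s in zip(c.values, c.scores):
                        fh.write(f"{c.variable},{x!r},{s!r}\n")
    else:
        report["overlay"] = {}

    # --- biomass -----------------------------------------------------------
    budget = _budget_from_overrides(config.constants_overrides)
    params = _params_from_overrides(config.constants_overrides)
    rate = biomass_monod.hydrogen_supply_rate(budget)
    scenarios = (
        ["full_ocean", "hydrothermal"] if config.scenario == "both"
        else [config.scenario]
    )
    report["biomass"] = {"hydrogen_budget": rate.to_dict(), "scenarios": {}}
    for sc in scenarios:
        report["biomass"]["scenarios"][sc] = biomass_monod.scenario_concentration(
            params, budget, sc, t=config.growth_horizon
        )
        if outdir is not None:
            St = report["biomass"]["scenarios"][sc]["St_mol_per_cm3_yr"]
            traj = biomass_monod.linear_growth(
                params, St, biomass_monod.default_time_grid(), scenario=sc
            )
            with open(outdir / f"trajectory_{sc}.csv", "w", encoding="utf-8") as fh:
                fh.write("t_yr,S_mol_per_cm3,X_g_per_cm3,cells_per_cm3\n")
                for row in zip(traj.times, traj.S, traj.X, traj.cells):
                    fh.write(",".join(repr(float(v)) for v in row) + "\n")

    report["elapsed_s"] = round(time.time() - t_start, 3)
    if outdir is not None:
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return report
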