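"""Configuration-driven experiment runner and result serialization.

An experiment chains geometry -> electrode placement -> lead-field solve ->
fiber population -> threshold search -> selectivity scoring, for one or more
electrode variants and fiber-population seeds, and writes a JSON summary,
per-configuration CSV tables and a plain-text log.  Identical configurations
produce identical outputs (every random stage is seeded).

Two named resolution/population profiles are provided: ``desk`` (coarse
grid, reduced fiber density, single seed — minutes on a laptop) and
``paper`` (fine grid, anatomical 240 fibers/mm^2, 10 seeds).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from enm.biophysics import IntegrationSettings, StimulusSweep
from enm.electrodes import build_fine, build_time, place_implants
from enm.fibers import DEFAULT_DENSITY, fibers_frame, populate_fibers
from enm.geometry import load_cross_section, synthesize_cross_section
from enm.selectivity import SelectivityEvaluator
from enm.volume_conductor import GridSpec, LeadFieldSolver, build_conductivity_map

PROFILES = {
    "desk": {"grid": GridSpec.coarse(), "density": 48.0, "seeds": (1,)},
    "paper": {"grid": GridSpec.fine(), "density": DEFAULT_DENSITY, "seeds": tuple(range(1, 11))},
}


class ExperimentError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    """Flat experiment description (YAML with dotted keys)."""

    anatomy: str = "distal"
    anatomy_seed: int = 1
    contour_file: str | None = None
    electrode_kind: str = "TIME"
    n_as: tuple = (12,)
    n_implants: int = 1
    placement_strategy: str = "evenly-spaced"
    placement_seed: int = 0
    policy: str = "monopolar"
    fiber_seeds: tuple = (1,)
    fiber_density: float = 48.0
    grid_profile: str = "coarse"  # coarse | default | fine
    sweep_min_nc: float = 0.5
    sweep_max_nc: float = 60.0
    sweep_n: int = 60
    pulse_us: float = 50.0
    out_dir: str = "enm-results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mapping = {
            "anatomy": "anatomy",
            "anatomy.seed": "anatomy_seed",
            "anatomy.contours": "contour_file",
            "electrode.kind": "electrode_kind",
            "electrode.n_as": "n_as",
            "placement.n_implants": "n_implants",
            "placement.strategy": "placement_strategy",
            "placement.seed": "placement_seed",
            "policy": "policy",
            "fibers.seeds": "fiber_seeds",
            "fibers.density": "fiber_density",
            "solver.grid": "grid_profile",
            "stim.min_nc": "sweep_min_nc",
            "stim.max_nc": "sweep_max_nc",
            "stim.n": "sweep_n",
            "stim.pulse_us": "pulse_us",
            "out": "out_dir",
        }
        kwargs = {}
        for key, val in raw.items():
            if key not in mapping:
                raise ExperimentError(f"unknown configuration key {key!r}")
            kwargs[mapping[key]] = tuple(val) if isinstance(val, list) else val
        cfg = cls(**kwargs)
        if isinstance(cfg.n_as, int):
            cfg.n_as = (cfg.n_as,)
        if isinstance(cfg.fiber_seeds, int):
            cfg.fiber_seeds = (cfg.fiber_seeds,)
        return cfg

    def grid(self) -> GridSpec:
        return {"coarse": GridSpec.coarse(), "default": GridSpec(), "fine": GridSpec.fine()}[
            self.grid_profile
        ]

    def sweep(self) -> StimulusSweep:
        return StimulusSweep(self.pulse_us, self.sweep_min_nc, self.sweep_max_nc, self.sweep_n)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


class Workbench:
    """Shared caches (geometry, lead fields, populations) across experiment
    stages and across experiments in one process."""

    def __init__(self):
        self._sections = {}
        self._fields = {}
        self._pops = {}

    def cross_section(self, config: ExperimentConfig):
        if config.contour_file:
            return load_cross_section(config.contour_file)
        key = (config.anatomy, config.anatomy_seed)
        if key not in self._sections:
            self._sections[key] = synthesize_cross_section(*key)
        return self._sections[key]

    def lead_fields(self, config: ExperimentConfig, cross_section, placements):
        key = (
            config.anatomy, config.anatomy_seed, config.contour_file, config.grid_profile,
            tuple(
                (pl.electrode.kind, pl.electrode.n_as, round(pl.insertion_point[0], 6),
                 round(pl.insertion_point[1], 6), pl.z_center)
                for pl in placements
            ),
        )
        if key not in self._fields:
            out = {}
            # one solve batch per placement: a shaft's lead fields are computed
            # with only that shaft present (thin neighbours are transparent)
            for pi, pl in enumerate(placements):
                cmap = build_conductivity_map(cross_section, [pl], config.grid())
                solver = LeadFieldSolver(cmap)
                for a in range(pl.electrode.n_as):
                    out[(pi, a)] = solver.solve_as((0, a))
            self._fields[key] = out
        return self._fields[key]

    def populations(self, config: ExperimentConfig, cross_section, fiber_seed: int):
        key = (config.anatomy, config.anatomy_seed, config.contour_file, fiber_seed,
               round(config.fiber_density, 6))
        if key not in self._pops:
            self._pops[key] = populate_fibers(cross_section, fiber_seed, config.fiber_density)
        return self._pops[key]


def _electrode(config: ExperimentConfig, n_as: int):
    builder = {"TIME": build_time, "FINE": build_fine}.get(config.electrode_kind)
    if builder is None:
        raise ExperimentError(f"unknown electrode kind {config.electrode_kind!r}")
    return builder(n_as, config.anatomy)


def run_experiment(
    config: ExperimentConfig,
    workbench: Workbench | None = None,
    settings: IntegrationSettings | None = None,
    write: bool = True,
) -> dict:
    """Execute the full pipeline for every (n_as, fiber seed) combination.

    Returns the result bundle (also written to ``out_dir`` as JSON + CSV +
    log unless ``write=False``): per variant the selectivity score mean and
    SD across fiber seeds, the selective fascicle sets, and for bipolar
    policies the improvement over monopolar on identical inputs.
    """
    wb = workbench or Workbench()
    t_start = time.time()
    log: list[str] = [f"config-hash {config.config_hash()}"]

    def stage(name):
        log.append(f"[{time.time() - t_start:8.1f}s] {name}")

    try:
        cross_section = wb.cross_section(config)
    except Exception as exc:
        raise ExperimentError(f"geometry stage failed: {exc}") from exc
    stage(f"geometry: {cross_section.n_fascicles} fascicles ({config.anatomy})")

    results = {"config": asdict(config), "variants": {}, "log": log}
    for n_as in config.n_as:
        electrode = _electrode(config, n_as)
        placements = place_implants(
            cross_section, electrode, config.n_implants,
            config.placement_strategy, config.placement_seed,
        )
        try:
            fields = wb.lead_fields(config, cross_section, placements)
        except Exception as exc:
            raise ExperimentError(f"solve stage failed ({config.electrode_kind}-{n_as}): {exc}") from exc
        stage(f"solve: {config.electrode_kind}-{n_as} x{len(placements)} "
              f"({len(fields)} lead fields)")
        scores, improvements, unions, tables = [], [], [], []
        for fs in config.fiber_seeds:
            pops = wb.populations(config, cross_section, fs)
            ev = SelectivityEvaluator(
                cross_section, placements, fields, pops,
                sweep=config.sweep(), settings=settings, anatomy=config.anatomy,
            )
            rep = ev.evaluate(config.policy)
            if config.policy in ("bipolar", "combined"):
                mono_union = set()
                for cfg_ in ev.policy_configs("monopolar"):
                    mono_union |= ev.config_selective_set(cfg_)
                rep.improvement = rep.score - 100.0 * len(mono_union) / ev.m
            scores.append(rep.score)
            improvements.append(rep.improvement)
            unions.append(sorted(rep.selective_union))
            tables.append(rep.table().assign(fiber_seed=fs))
            stage(f"evaluate: {config.electrode_kind}-{n_as} seed {fs} "
                  f"score {rep.score:.1f}%")
        variant = {
            "electrode": f"{config.electrode_kind}-{n_as}",
            "scores": scores,
            "score_mean": float(np.mean(scores)),
            "score_sd": float(np.std(scores)),
            "selective_fascicles": unions,
            "fiber_seeds": list(config.fiber_seeds),
        }
        if config.policy in ("bipolar", "combined"):
            variant["improvement_mean"] = float(np.mean([i for i in improvements if i is not None]))
        results["variants"][f"{config.electrode_kind}-{n_as}"] = variant
        results.setdefault("_tables", {})[f"{config.electrode_kind}-{n_as}"] = tables

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = results.pop("_tables", {})
        (out / "report.json").write_text(json.dumps(results, indent=1, default=str))
        for name, tabs in tables.items():
            import pandas as pd

            pd.concat(tabs).to_csv(out / f"selectivity_{name}.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    else:
        results.pop("_tables", None)
    return results


def compare_policies(report_mono: dict, report_bi: dict) -> dict:
    """Per-electrode improvement (percentage points) of bipolar over monopolar
    evaluated on identical geometry and fiber seeds."""
    for k in ("anatomy", "anatomy_seed", "fiber_seeds"):
        if report_mono["config"][k] != report_bi["config"][k]:
            raise ExperimentError(f"reports differ in {k}; comparison undefined")
    out = {}
    for name, mono in report_mono["variants"].items():
        bi = report_bi["variants"].get(name)
        if bi is None:
            continue
        newly = [
            sorted(set(b) - set(a))
            for a, b in zip(mono["selective_fascicles"], bi["selective_fascicles"])
        ]
        out[name] = {
            "improvement_points": bi["score_mean"] - mono["score_mean"],
            "newly_selective": newly,
        }
    return out
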