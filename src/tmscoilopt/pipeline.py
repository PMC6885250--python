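"""Study orchestration: phantom -> repeated PSO -> exhaustive check -> metrics.

Mirrors the evaluation protocol of the per-model study: the optimization
is repeated with several seeds that differ only in the initial particle
placement, per-run rows are tabulated alongside a mean +/- standard
deviation summary, the swarm optimum is optionally validated against the
exhaustive grid-search oracle, and the cortical-complexity metrics of the
search patch are recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coil as coil_mod
from . import cortex, gridsearch, pso
from . import phantom as phantom_mod
from .model_io import save_field_volume, save_voxel_model

logger = logging.getLogger("tmscoilopt")


@dataclass
class CoilSpec:
    loop_radius_mm: float = coil_mod.DEFAULT_LOOP_RADIUS_MM
    n_segments: int = coil_mod.DEFAULT_N_SEGMENTS
    current_A: float = coil_mod.DEFAULT_CURRENT_A
    frequency_Hz: float = coil_mod.DEFAULT_FREQUENCY_HZ

    def build(self) -> coil_mod.CoilGeometry:
        return coil_mod.build_foe_coil(self.loop_radius_mm, self.n_segments,
                                       self.current_A, self.frequency_Hz)


@dataclass
class RunConfig:
    """Validated configuration of a full study."""

    phantom: phantom_mod.PhantomSpec = field(
        default_factory=phantom_mod.PhantomSpec)
    coil: CoilSpec = field(default_factory=CoilSpec)
    pso: pso.PSOConfig = field(default_factory=pso.PSOConfig)
    grid: gridsearch.GridSearchSpec | None = None
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    output_dir: str = "study_out"
    log_level: str = "INFO"
    write_volumes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "phantom" in raw:
            kwargs["phantom"] = phantom_mod.PhantomSpec(**raw["phantom"])
        if "coil" in raw:
            kwargs["coil"] = CoilSpec(**raw["coil"])
        if "pso" in raw:
            kwargs["pso"] = pso.PSOConfig(**raw["pso"])
        if raw.get("grid") is not None:
            kwargs["grid"] = gridsearch.GridSearchSpec(**raw["grid"])
        for key in ("seeds", "output_dir", "log_level", "write_volumes"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "seeds" else raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (not output/log settings)."""
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)
        payload = dataclasses.asdict(self)
        for key in ("output_dir", "log_level", "write_volumes"):
            payload.pop(key, None)
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:10]


@dataclass
class StudyReport:
    rows: pd.DataFrame                 # one row per seeded run
    summary: pd.DataFrame              # mean +/- sd over the runs
    metrics: cortex.CortexMetrics
    comparison: gridsearch.ComparisonReport | None
    config_hash: str


def result_row(res: pso.OptimizationResult) -> dict:
    return {
        "seed": res.seed,
        "iterations": res.iterations,
        "initial_V_per_m": res.initial_val,
        "optimized_V_per_m": res.best_val,
        "enhancement_pct": res.enhancement_pct,
        "displacement_mm": res.displacement_mm,
        "phi_deg": res.phi_deg,
        "n_evaluations": res.n_evaluations,
        "converged": res.converged,
    }


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    cols = ["iterations", "enhancement_pct", "displacement_mm", "phi_deg"]
    return pd.DataFrame({
        "mean": rows[cols].mean(),
        "sd": rows[cols].std(ddof=0),
    })


def run_study(config: RunConfig) -> StudyReport:
    """Run the full pipeline and write all outputs under ``output_dir``.

    Stages: phantom generation, one PSO run per seed (seeds differ only in
    the initial particle placement), optional exhaustive validation against
    the best-objective run, and cortical metrics of the search patch.
    Outputs (CSV/JSON/NIfTI) are tagged with the config hash.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()

    model, roi, ip = phantom_mod.make_gyrified_phantom(config.phantom)
    geom = config.coil.build()
    patch = pso.search_patch_for(model, ip)
    objective = pso.EFieldObjective(model, geom, roi, patch)

    results: list[pso.OptimizationResult] = []
    for seed in config.seeds:
        cfg = dataclasses.replace(config.pso, seed=int(seed))
        res = pso.run_pso(objective, patch, ip, cfg)
        results.append(res)
        logger.info("seed %d: %d iterations, enhancement %.2f%%",
                    seed, res.iterations, res.enhancement_pct)

    rows = pd.DataFrame([result_row(r) for r in results])
    summary = summarize(rows)

    comparison = None
    if config.grid is not None:
        grid_res = gridsearch.run_exhaustive(config.grid, objective, patch)
        best_run = max(results, key=lambda r: r.best_val)
        comparison = gridsearch.compare(best_run, grid_res)
        counts, edges = gridsearch.objective_histogram(grid_res)
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                      "count": counts}).to_csv(
            out / f"grid_histogram_{tag}.csv", index=False)
        (out / f"comparison_{tag}.json").write_text(
            json.dumps(dataclasses.asdict(comparison), indent=1))

    region = cortex.PatchRegion(center=ip.center, normal=ip.normal,
                                half_extent_mm=patch.half_extent)
    metrics = cortex.cortex_metrics(model, region)

    rows.to_csv(out / f"runs_{tag}.csv", index=False)
    summary.to_csv(out / f"summary_{tag}.csv")
    (out / f"metrics_{tag}.json").write_text(json.dumps({
        "lgi": metrics.lgi, "fd": metrics.fd,
        "fd_r_squared": metrics.fd_r_squared,
        "fd_counts": {str(k): v for k, v in metrics.fd_counts.items()},
    }, indent=1))

    if config.write_volumes:
        save_voxel_model(model, out / f"phantom_{tag}.nii.gz")
        best_run = max(results, key=lambda r: r.best_val)
        e = objective.efield_volume(best_run.best_pos)
        save_field_volume(np.nan_to_num(e.e), e.spacing, e.origin,
                          out / f"efield_best_{tag}.nii.gz")

    history = pd.concat([
        pd.DataFrame({"seed": r.seed, "iteration": range(len(r.history)),
                      "gbest_V_per_m": r.history}) for r in results])
    history.to_csv(out / f"history_{tag}.csv", index=False)

    return StudyReport(rows=rows, summary=summary, metrics=metrics,
                       comparison=comparison, config_hash=tag)
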