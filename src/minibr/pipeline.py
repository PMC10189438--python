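"""End-to-end pipeline: gate -> flow -> suspension -> stress -> summaries.

`run_pipeline` chains the stages with deterministic artifacts: rerunning
with the same configuration and seed reproduces byte-identical numerical
outputs (the manifest records content hashes to prove it).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

from .config import ProcessConfig, save_config
from .dimensionless import regime_report
from .exceptions import LaminarGateError
from .flow import solve_flow
from .io import (file_sha256, write_flow_csv, write_flow_vtk, write_json,
                 write_stress_traces_csv, write_summary_csv,
                 write_trajectories_csv)
from .stress import classify, population_summary, stress_history
from .suspension import simulate

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """What a run produced, with content hashes for reproducibility."""

    config_file: str
    seed: int
    outputs: dict          # name -> {"path": ..., "sha256": ...}
    percentiles_mpa: dict
    stagnant_fraction: float
    wall_time_s: float


def run_pipeline(cfg: ProcessConfig, outdir, *,
                 force: bool = False) -> RunManifest:
    """Execute check -> flow -> simulate -> stress -> summary, write files.

    Aborts with :class:`LaminarGateError` when the laminar gate fails and
    ``force`` is not set; any stage error propagates with its own type.
    """
    t_start = time.perf_counter()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = regime_report(cfg)
    if not report.laminar_ok and not force:
        raise LaminarGateError(
            f"Re_f = {report.fluid_reynolds:.0f} fails the laminar gate; "
            "use force to override")

    cfg_path = outdir / "config.yaml"
    save_config(cfg, cfg_path)

    field = solve_flow(cfg.vessel, cfg.fluid, cfg.impeller,
                       resolution=cfg.grid, force=force)
    trajectories = simulate(cfg, field, force=force)
    traces = [stress_history(traj, field, cfg.fluid)
              for traj in trajectories]
    labels = classify(trajectories, cfg.vessel, cfg.impeller,
                      min_duration=min(10.0, cfg.duration))
    summary = population_summary(traces, trajectories, cfg.vessel,
                                 cfg.impeller, regime=cfg.regime)

    paths = {
        "flow_vtk": outdir / "flow.vtk",
        "flow_csv": outdir / "flow.csv",
        "trajectories": outdir / "trajectories.csv",
        "stress_traces": outdir / "stress_traces.csv",
        "summary": outdir / "summary.csv",
        "report": outdir / "report.json",
    }
    write_flow_vtk(field, cfg.fluid, paths["flow_vtk"])
    write_flow_csv(field, paths["flow_csv"])
    write_trajectories_csv(trajectories, paths["trajectories"])
    write_stress_traces_csv(traces, paths["stress_traces"])
    write_summary_csv(traces, labels, paths["summary"])

    percentiles_mpa = {str(k): v * 1e3
                       for k, v in summary.percentiles.items()}
    write_json({
        "regime": cfg.regime,
        "omega_rad_s": cfg.impeller.angular_velocity,
        "n_particles": cfg.n_particles,
        "duration_s": cfg.duration,
        "percentiles_mPa": percentiles_mpa,
        "stagnant_fraction": summary.stagnant_fraction,
        "dimensionless": {
            "Re_f": report.fluid_reynolds,
            "Stk": report.stokes_number,
            "Re_p": report.particle_reynolds,
        },
    }, paths["report"])

    outputs = {name: {"path": str(p), "sha256": file_sha256(p)}
               for name, p in paths.items()}
    manifest = RunManifest(config_file=str(cfg_path), seed=cfg.seed,
                           outputs=outputs,
                           percentiles_mpa=percentiles_mpa,
                           stagnant_fraction=summary.stagnant_fraction,
                           wall_time_s=time.perf_counter() - t_start)
    write_json(asdict(manifest), outdir / "manifest.json")
    return manifest
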