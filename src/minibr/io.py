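"""Plain-text output writers: legacy VTK, CSV tables, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import FluidProperties
from .flow import FlowField
from .stress import StressTrace
from .suspension import Trajectory

__all__ = [
    "write_flow_vtk",
    "write_flow_csv",
    "write_trajectories_csv",
    "write_stress_traces_csv",
    "write_summary_csv",
    "file_sha256",
]


def write_flow_vtk(field: FlowField, fluid: FluidProperties, path) -> None:
    """Write the (r, z) field as a legacy ASCII VTK rectilinear grid.

    Point data: the meridional-plane velocity vector (u_r, u_theta, u_z
    mapped onto x/y/z slots), the swirl component, and the fluid von Mises
    stress 2 mu sqrt(1.5 E:E).
    """
    nr, nz = field.shape
    e = field.strain
    vm = 2.0 * fluid.viscosity * np.sqrt(1.5 * (
        e[0] ** 2 + e[1] ** 2 + e[2] ** 2
        + 2.0 * (e[3] ** 2 + e[4] ** 2 + e[5] ** 2)))
    lines = [
        "# vtk DataFile Version 3.0",
        "miniBR axisymmetric flow field (r,z plane)",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nr} {nz} 1",
        f"X_COORDINATES {nr} double",
        " ".join(f"{v:.9e}" for v in field.r),
        f"Y_COORDINATES {nz} double",
        " ".join(f"{v:.9e}" for v in field.z),
        "Z_COORDINATES 1 double",
        "0.0",
        f"POINT_DATA {nr * nz}",
        "VECTORS velocity double",
    ]
    # VTK orders points with x (here r) fastest
    for j in range(nz):
        for i in range(nr):
            lines.append(f"{field.u_r[i, j]:.9e} {field.u_theta[i, j]:.9e} "
                         f"{field.u_z[i, j]:.9e}")
    lines.append("SCALARS swirl double 1")
    lines.append("LOOKUP_TABLE default")
    for j in range(nz):
        for i in range(nr):
            lines.append(f"{field.u_theta[i, j]:.9e}")
    lines.append("SCALARS von_mises_stress double 1")
    lines.append("LOOKUP_TABLE default")
    for j in range(nz):
        for i in range(nr):
            lines.append(f"{vm[i, j]:.9e}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_flow_csv(field: FlowField, path) -> None:
    """Nodal values, one row per (r, z) node."""
    nr, nz = field.shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nz), indexing="ij")
    df = pd.DataFrame({
        "r_m": field.r[ii.ravel()],
        "z_m": field.z[jj.ravel()],
        "u_r": field.u_r.ravel(),
        "u_theta": field.u_theta.ravel(),
        "u_z": field.u_z.ravel(),
        "p": field.p.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.9e")


def write_trajectories_csv(trajectories: Sequence[Trajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(pd.DataFrame({
            "particle_id": traj.particle_id,
            "t_s": traj.t,
            "x_m": traj.position[:, 0],
            "y_m": traj.position[:, 1],
            "z_m": traj.position[:, 2],
            "vx": traj.velocity[:, 0],
            "vy": traj.velocity[:, 1],
            "vz": traj.velocity[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9e")


def write_stress_traces_csv(traces: Sequence[StressTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "particle_id": tr.particle_id,
            "t_s": tr.t,
            "von_mises_Pa": tr.von_mises,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9e")


def write_summary_csv(traces: Sequence[StressTrace], labels, path) -> None:
    df = pd.DataFrame({
        "particle_id": [tr.particle_id for tr in traces],
        "mean_stress_Pa": [tr.average for tr in traces],
        "class": list(labels),
    })
    df.to_csv(path, index=False, float_format="%.9e")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
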