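"""Trajectory writers: per-sample CSV, summary traces, legacy ASCII VTK."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import spatial_summary

__all__ = ["write_field_csv", "write_cell_csv", "write_summary_csv",
           "write_vtk_series", "write_trajectory"]


def write_field_csv(trajectory, out_dir):
    """One CSV per sample: node id, x, y, then one column per species."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = trajectory.mesh
    paths = []
    for i, (t, values) in enumerate(zip(trajectory.times, trajectory.fields)):
        df = pd.DataFrame({
            "node": np.arange(mesh.n_nodes),
            "x": mesh.node_xy[:, 0],
            "y": mesh.node_xy[:, 1],
        })
        for k, name in enumerate(trajectory.species):
            df[name] = values[:, k]
        path = out / f"field_{i:05d}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths.append(path)
    return paths


def write_cell_csv(trajectory, out_path):
    """Flat CSV of all per-sample cell records (empty if no cells)."""
    rows = [row for sample in trajectory.cell_records for row in sample]
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False, float_format="%.10g")
    return out_path


def write_summary_csv(trajectory, out_path):
    """Spatially averaged traces: mean/min/max/quartiles per species."""
    summary = spatial_summary(trajectory)
    frames = []
    for name, stats in summary.items():
        df = pd.DataFrame(stats)
        df.insert(0, "species", name)
        frames.append(df)
    pd.concat(frames).to_csv(out_path, index=False, float_format="%.10g")
    return out_path


def write_vtk_series(trajectory, out_dir, prefix="field"):
    """Legacy ASCII VTK unstructured-grid snapshots (one file per sample)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = trajectory.mesh
    paths = []
    for i, values in enumerate(trajectory.fields):
        lines = [
            "# vtk DataFile Version 3.0",
            f"t = {trajectory.times[i]:g}",
            "ASCII",
            "DATASET UNSTRUCTURED_GRID",
            f"POINTS {mesh.n_nodes} double",
        ]
        lines += [f"{x:g} {y:g} 0" for x, y in mesh.node_xy]
        lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
        lines += ["3 " + " ".join(map(str, t)) for t in mesh.triangles]
        lines.append(f"CELL_TYPES {mesh.n_elements}")
        lines += ["5"] * mesh.n_elements            # VTK_TRIANGLE
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for k, name in enumerate(trajectory.species):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:g}" for v in values[:, k]]
        path = out / f"{prefix}_{i:05d}.vtk"
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def write_trajectory(trajectory, out_dir, vtk=False):
    """Write the standard output set for a run under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_field_csv(trajectory, out / "fields")
    write_summary_csv(trajectory, out / "summary.csv")
    if trajectory.cell_records:
        write_cell_csv(trajectory, out / "cells.csv")
    if vtk:
        write_vtk_series(trajectory, out / "vtk")
    return out
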