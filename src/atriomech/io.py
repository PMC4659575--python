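"""Trace/field/mesh IO and run manifests.

Cell traces go to CSV or HDF5; tissue field frames to HDF5; 2D sheets can be
exported as legacy-VTK ASCII structured points for visualisation; surface
meshes round-trip through OFF/PLY (via trimesh).  Every CLI run writes a JSON
manifest (config, seed, package/dependency versions, output hashes) that is
sufficient to reproduce deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "save_parameters",
    "load_parameters",
    "save_trace_csv",
    "save_trace_h5",
    "load_trace_h5",
    "save_fields_h5",
    "write_vtk_sheet",
    "save_mesh",
    "load_mesh",
    "write_manifest",
]


def save_parameters(params, path) -> Path:
    """Cell parameters as a flat key-value YAML (or JSON by suffix) file."""
    from dataclasses import asdict

    import yaml

    path = Path(path)
    payload = {k: float(v) for k, v in asdict(params).items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_parameters(path):
    """Read a flat key-value parameter file back into CellParameters."""
    import yaml

    from .ionic import CellParameters

    text = Path(path).read_text()
    payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return CellParameters(**payload).validate()


def save_trace_csv(trace, path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    return path


def save_trace_h5(trace, path) -> Path:
    path = Path(path)
    df = trace.to_frame()
    with h5py.File(path, "w") as f:
        for col in df.columns:
            f.create_dataset(col, data=df[col].to_numpy())
        f.attrs["region"] = trace.region
        f.attrs["remodeling"] = trace.remodeling
        f.attrs["stim_amplitude_pA"] = trace.stim_amplitude
        f.attrs["SL0_um"] = trace.SL0
    return path


def load_trace_h5(path) -> dict:
    with h5py.File(path, "r") as f:
        data = {k: f[k][...] for k in f.keys()}
        data.update({k: f.attrs[k] for k in f.attrs})
    return data


def save_fields_h5(trace, grid, path) -> Path:
    """Tissue frames (V, gamma) plus grid metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=trace.t)
        f.create_dataset("V", data=trace.V)
        if trace.gamma is not None:
            f.create_dataset("gamma", data=trace.gamma)
        f.create_dataset("activation_time", data=trace.activation_time)
        f.create_dataset("activation_count", data=trace.activation_count)
        f.attrs["shape"] = grid.shape
        f.attrs["dx_mm"] = grid.dx
    return path


def write_vtk_sheet(field: np.ndarray, dx: float, path, name: str = "V") -> Path:
    """One 2D nodal field as legacy-VTK ASCII structured points."""
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("write_vtk_sheet expects a 2D field")
    ny, nx = field.shape
    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\natriomech sheet\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {dx} {dx} 1\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, field.ravel()[:, None], fmt="%.6g")
    return path


def save_mesh(vertices, faces, path) -> Path:
    """OFF or PLY export by file suffix."""
    import trimesh

    path = Path(path)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(path)
    return path


def load_mesh(path):
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=int)


def _versions() -> dict:
    import importlib.metadata as md

    out = {"python": platform.python_version()}
    for pkg in ("atriomech", "numpy", "scipy", "numba", "pandas", "h5py", "trimesh"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def write_manifest(path, config: dict, seed=None, outputs=()) -> Path:
    """JSON manifest: config, seed, versions, sha256 of each output file."""
    path = Path(path)
    hashes = {}
    for out in outputs:
        out = Path(out)
        if out.exists():
            hashes[out.name] = hashlib.sha256(out.read_bytes()).hexdigest()
    payload = {
        "config": config,
        "seed": seed,
        "versions": _versions(),
        "outputs": hashes,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
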