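"""Readers/writers for the standard formats, run configuration and provenance.

Velocity fields travel as NIfTI: either a single 5-D file
(x, y, z, time, component) or three 4-D files, one per component, with
a JSON sidecar carrying the frame interval and velocity unit.  Voxel
spacing is stored in the NIfTI affine in millimetres (the medical
convention) and converted to SI metres on read.  Label volumes are
integer NIfTI (0 exterior, 1 interior, 2 inlet, 3 outlet, 4 wall);
planes are JSON; traces are CSV with columns time_s, dp_pa, dp_mmhg;
solved virtual fields are cached to HDF5 keyed by a configuration hash
so repeated pressure queries on the same domain reuse the solve.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import (
    DomainLabels,
    FluidProperties,
    Plane,
    VelocityField4D,
    VoxelGrid,
)
from .virtual_field import StokesSolverConfig, VirtualField

__all__ = [
    "read_flow",
    "write_flow",
    "read_labels",
    "write_labels",
    "read_plane",
    "write_plane",
    "save_virtual_field",
    "load_virtual_field",
    "RunConfig",
    "run_pipeline",
]

_UNIT_SCALE = {"m/s": 1.0, "cm/s": 0.01, "mm/s": 0.001}


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(3):
        aff[a, a] = grid.spacing[a] * 1000.0  # metres -> mm
        aff[a, 3] = grid.origin[a] * 1000.0
    return aff


def _grid_from(img) -> VoxelGrid:
    aff = img.affine
    spacing = tuple(abs(float(aff[a, a])) / 1000.0 for a in range(3))
    origin = tuple(float(aff[a, 3]) / 1000.0 for a in range(3))
    return VoxelGrid(img.shape[:3], spacing, origin)


def write_flow(field: VelocityField4D, path) -> None:
    """Write a velocity field as one 5-D NIfTI plus a JSON sidecar."""
    path = Path(path)
    # (nt, nx, ny, nz, 3) -> (nx, ny, nz, nt, 3)
    data = np.moveaxis(field.values, 0, 3).astype(np.float64)
    img = nib.Nifti1Image(data, _affine(field.grid))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"dt_s": field.dt, "velocity_unit": "m/s", "frames": field.frames})
    )


def read_flow(path, dt: float | None = None, velocity_unit: str | None = None) -> VelocityField4D:
    """Read a velocity field from one 5-D NIfTI or three 4-D component files.

    ``path`` may be a single file or a sequence of three per-component
    files (x, y, z order).  The frame interval and unit come from the
    JSON sidecar unless overridden.
    """
    if isinstance(path, (list, tuple)):
        return _read_components(path, dt, velocity_unit)
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 5 or data.shape[-1] != 3:
        raise ValueError(
            f"expected a 5-D (x,y,z,t,3) velocity image, got shape {data.shape}"
        )
    grid = _grid_from(img)
    meta = {}
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    dt = dt if dt is not None else meta.get("dt_s")
    if dt is None:
        raise ValueError("frame interval dt not given and no sidecar found")
    unit = velocity_unit or meta.get("velocity_unit", "m/s")
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown velocity unit {unit!r}")
    values = np.moveaxis(data, 3, 0) * _UNIT_SCALE[unit]
    return VelocityField4D(grid, dt, values)


def _read_components(paths, dt, velocity_unit):
    if len(paths) != 3:
        raise ValueError("expected exactly three component files (x, y, z)")
    imgs = [nib.load(Path(p)) for p in paths]
    shapes = [im.shape for im in imgs]
    if len(set(shapes)) != 1:
        raise ValueError(f"inconsistent component geometries: {shapes}")
    grids = [_grid_from(im) for im in imgs]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError("inconsistent spacing/origin across component files")
    data = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs], axis=-1)
    if data.ndim != 5:
        raise ValueError("component files must be 4-D (x, y, z, t)")
    meta = {}
    sidecar = Path(paths[0]).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    dt = dt if dt is not None else meta.get("dt_s")
    if dt is None:
        raise ValueError("frame interval dt not given and no sidecar found")
    unit = velocity_unit or meta.get("velocity_unit", "m/s")
    values = np.moveaxis(data, 3, 0) * _UNIT_SCALE[unit]
    return VelocityField4D(grids[0], dt, values)


def write_labels(labels: DomainLabels, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.grid))
    nib.save(img, Path(path))


def read_labels(path) -> DomainLabels:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("label volume must be 3-D")
    return DomainLabels(_grid_from(img), data.astype(np.int8))


def write_plane(plane: Plane, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "voxels": plane.voxels.tolist(),
                "normal": plane.normal.tolist(),
                "seed": list(plane.seed) if plane.seed is not None else None,
                "role": plane.role,
            }
        )
    )


def read_plane(path) -> Plane:
    d = json.loads(Path(path).read_text())
    return Plane(
        np.asarray(d["voxels"], dtype=int),
        np.asarray(d["normal"], dtype=float),
        seed=tuple(d["seed"]) if d.get("seed") else None,
        role=d.get("role", "inlet"),
    )


def save_virtual_field(vf: VirtualField, path, key: str = "vf") -> None:
    """Cache a solved virtual field (w, lambda, labels, faces) to HDF5."""
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("w", data=vf.w, compression="gzip")
        g.create_dataset("lam", data=vf.lam, compression="gzip")
        g.create_dataset("labels", data=vf.labels.labels, compression="gzip")
        g.create_dataset("inlet_normal", data=vf.inlet_normal)
        g.attrs["spacing"] = vf.grid.spacing
        g.attrs["origin"] = vf.grid.origin
        g.attrs["diagnostics"] = json.dumps(
            {k: v for k, v in vf.diagnostics.items() if np.isscalar(v)}
        )
        if vf.faces is not None:
            fg = g.create_group("faces")
            fg.attrs["inlet_scale"] = vf.faces["inlet_scale"]
            for a in range(3):
                fg.create_dataset(f"values{a}", data=vf.faces["values"][a],
                                  compression="gzip")
                fg.create_dataset(f"status{a}", data=vf.faces["status"][a],
                                  compression="gzip")


def load_virtual_field(path, key: str = "vf") -> VirtualField:
    with h5py.File(path, "r") as f:
        g = f[key]
        lab = g["labels"][()]
        grid = VoxelGrid(lab.shape, tuple(g.attrs["spacing"]), tuple(g.attrs["origin"]))
        faces = None
        if "faces" in g:
            fg = g["faces"]
            faces = {
                "values": [fg[f"values{a}"][()] for a in range(3)],
                "status": [fg[f"status{a}"][()] for a in range(3)],
                "inlet_scale": float(fg.attrs["inlet_scale"]),
            }
        return VirtualField(
            grid,
            g["w"][()],
            g["lam"][()],
            DomainLabels(grid, lab.astype(np.int8)),
            g["inlet_normal"][()],
            json.loads(g.attrs["diagnostics"]),
            faces,
        )


@dataclass
class RunConfig:
    """Everything needed to reproduce an estimation run from files."""

    flow: str
    labels: str | None = None
    inlet: str | None = None
    outlet: str | None = None
    method: str = "vwerp"
    rho: float = 1060.0
    mu: float = 4.0e-3
    dt: float | None = None
    velocity_unit: str = "m/s"
    filter_order: int | None = None
    filter_kernel: int | None = None
    snr: float | None = None
    subsample_spacing: float | None = 0.5e-3
    tolerance: float = 1e-10
    out_dir: str = "."
    vf_cache: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute load -> labels -> virtual field -> energies -> trace.

    Writes trace.csv, energy.csv (where the method has a decomposition)
    and provenance.json into ``config.out_dir`` and returns the output
    paths plus headline numbers.
    """
    from .estimators import VwerpModel, WerpModel
    from .smoothing import FilterParams

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("flow", "labels", "inlet", "outlet"):
        p = getattr(config, name)
        if p is None:
            raise ValueError(f"configuration error: {name} input is required")
        if not Path(p).exists():
            raise ValueError(f"configuration error: {name} file {p!r} does not exist")
    field = read_flow(config.flow, dt=config.dt, velocity_unit=config.velocity_unit)
    labels = read_labels(config.labels)
    if labels.grid.shape != field.grid.shape:
        raise ValueError("labels and flow grids do not match")
    labels = DomainLabels(field.grid, labels.labels)
    inlet = read_plane(config.inlet)
    outlet = read_plane(config.outlet)
    fluid = FluidProperties(rho=config.rho, mu=config.mu)
    fp = None
    if config.filter_order is not None and config.filter_kernel is not None:
        fp = FilterParams(config.filter_order, config.filter_kernel)
    elif config.snr is not None:
        fp = "auto"
    scfg = StokesSolverConfig(
        subsample_spacing=config.subsample_spacing, tolerance=config.tolerance
    )
    vf = None
    if config.vf_cache and Path(config.vf_cache).exists():
        try:
            vf = load_virtual_field(config.vf_cache, key=config.hash())
        except KeyError:
            vf = None
    if config.method == "vwerp":
        model = VwerpModel(
            field, labels, inlet, outlet, fluid=fluid, filter_params=fp,
            solver_config=scfg, snr=config.snr, virtual_field=vf,
        )
        res = model.fit()
        if config.vf_cache and vf is None:
            save_virtual_field(res.virtual_field, config.vf_cache, key=config.hash())
    elif config.method == "werp":
        res = WerpModel(
            field, labels, inlet, outlet, fluid=fluid, filter_params=fp,
            snr=config.snr,
        ).fit()
    else:
        raise ValueError(f"run_pipeline supports vwerp/werp, got {config.method!r}")
    trace_path = out / "trace.csv"
    res.save_trace(trace_path)
    energy_path = out / "energy.csv"
    res.energy.to_dataframe().to_csv(energy_path, index=False)
    prov = {
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "method": res.method,
        "filter": dataclasses.asdict(res.filter_params),
        "diagnostics": {k: v for k, v in res.diagnostics.items() if np.isscalar(v)},
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2))
    return {
        "trace": str(trace_path),
        "energy": str(energy_path),
        "provenance": str(prov_path),
        "peak_dp_pa": float(np.nanmax(res.dp_pa)),
    }
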