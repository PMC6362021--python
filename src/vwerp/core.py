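"""Shared data model for voxelized vector fields, labeled domains and pressure traces.

Everything in this package lives on a uniform voxel grid: the measured
velocity image, the binary/label masks derived from it, and the auxiliary
(virtual) field used to project the momentum balance onto a vascular
segment.  The types here carry the geometry (spacing, origin, frame
timing) and the elementary integral operations (plane flux, midpoint
fields, unit conversion) that every other module builds on.

Conventions
-----------
* Voxel indices are 0-based; the physical position of voxel ``(i, j, k)``
  is ``origin + (i*dx, j*dy, k*dz)`` (voxel-center convention).
* All computations are in SI units (m, s, Pa, kg/m^3, Pa*s).  The
  mmHg conversion (1 mmHg = 133.322 Pa) is applied only at presentation.
* Velocity arrays are stored frame-major with a trailing component axis:
  ``(nt, nx, ny, nz, 3)``; single-frame fields drop the leading axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MMHG_PA",
    "EXTERIOR",
    "INTERIOR",
    "INLET",
    "OUTLET",
    "WALL",
    "VoxelGrid",
    "FluidProperties",
    "VelocityField4D",
    "DomainLabels",
    "Plane",
    "RelativePressureTrace",
    "flow_rate",
    "to_mmHg",
    "midpoint_field",
]

#: Pa per mmHg, applied only for display/serialization.
MMHG_PA = 133.322

# Integer label codes (also used in NIfTI label volumes).
EXTERIOR = 0
INTERIOR = 1
INLET = 2
OUTLET = 3
WALL = 4


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform voxel lattice: shape, spacing (m) and physical origin (m)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError("grid shape must be three positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("all voxel spacings must be strictly positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def dV(self) -> float:
        """Voxel volume dV = dx*dy*dz (m^3)."""
        return float(np.prod(self.spacing))

    def dS(self, normal=None) -> float:
        """Voxel cross-section area (m^2) for a plane of given unit normal.

        For an axis-aligned normal this is the product of the two
        transverse spacings; the general form ``dV / sum(|N_i| dx_i)``
        reduces to it and keeps staircase flux sums consistent.
        """
        if normal is None:
            return self.spacing[0] * self.spacing[1]
        n = np.asarray(normal, dtype=float)
        denom = float(np.abs(n) @ np.asarray(self.spacing))
        if denom <= 0:
            raise ValueError("degenerate plane normal")
        return self.dV / denom

    def positions(self, index_array) -> np.ndarray:
        """Physical coordinates (m) of voxel indices, voxel-center convention."""
        idx = np.asarray(index_array, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate vectors of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants: density rho (kg/m^3), viscosity mu (Pa*s).

    Defaults are conventional values for blood.
    """

    rho: float = 1060.0
    mu: float = 4.0e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass
class VelocityField4D:
    """Time-resolved 3-component velocity image v(x, t) in m/s.

    ``values`` has shape ``(nt, nx, ny, nz, 3)``; ``dt`` is the frame
    interval in seconds.  Voxels outside the fluid carry zeros.
    """

    grid: VoxelGrid
    dt: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError("values must have shape (nt, nx, ny, nz, 3)")
        if self.values.shape[1:4] != self.grid.shape:
            raise ValueError(
                f"values spatial shape {self.values.shape[1:4]} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")

    @property
    def frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.frames)

    @property
    def vmax(self) -> float:
        """Maximum velocity magnitude over the whole dataset."""
        return float(np.sqrt((self.values**2).sum(axis=-1)).max())

    def frame(self, n: int) -> np.ndarray:
        return self.values[n]

    def speed(self, n: int | None = None) -> np.ndarray:
        """Velocity magnitude of frame ``n`` (or all frames if None)."""
        v = self.values if n is None else self.values[n]
        return np.sqrt((v**2).sum(axis=-1))


@dataclass
class DomainLabels:
    """Per-voxel classification {exterior, interior, inlet, outlet, wall}.

    The interior set is the region of interest Omega_ROI; inlet/outlet
    voxels discretize the end planes Gamma_i / Gamma_o and wall voxels
    the lateral boundary Gamma_w.
    """

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape must match grid shape")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)

    @property
    def interior(self) -> np.ndarray:
        return self.labels == INTERIOR

    @property
    def fluid(self) -> np.ndarray:
        """Lumen voxels with valid flow data: interior + inlet + outlet."""
        return self.mask(INTERIOR, INLET, OUTLET)

    def count(self, code: int) -> int:
        return int((self.labels == code).sum())


@dataclass
class Plane:
    """A voxelized cross-sectional cut with an outward unit normal.

    ``voxels`` is an ``(n, 3)`` integer index array; ``normal`` is the
    outward normal N of the region of interest at this plane; ``seed``
    is the user-selected surface point the plane was grown from.
    """

    voxels: np.ndarray
    normal: np.ndarray
    seed: tuple[int, int, int] | None = None
    role: str = "inlet"

    def __post_init__(self):
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError("degenerate plane: no voxels")
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = n / nn
        if self.role not in ("inlet", "outlet"):
            raise ValueError("role must be 'inlet' or 'outlet'")

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def flip(self) -> "Plane":
        return Plane(self.voxels.copy(), -self.normal, self.seed, self.role)


@dataclass
class RelativePressureTrace:
    """Relative pressure Delta-p(t) at time midpoints, stored in Pa.

    For an N-frame input every estimator in this package produces N-1
    samples at the midpoints t_{n+1/2}.  Conversion to mmHg happens only
    on access, never inside any computation.
    """

    times: np.ndarray
    dp_pa: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dp_pa = np.asarray(self.dp_pa, dtype=float)
        if self.times.shape != self.dp_pa.shape or self.times.ndim != 1:
            raise ValueError("times and dp_pa must be matching 1-D arrays")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dp_mmhg(self) -> np.ndarray:
        return to_mmHg(self.dp_pa)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "dp_pa": self.dp_pa, "dp_mmhg": self.dp_mmhg}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RelativePressureTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["dp_pa"].to_numpy())


def flow_rate(field_values, plane: Plane, grid: VoxelGrid) -> float:
    """Volumetric flow through a voxelized plane: Q = dS * sum(f . N).

    ``field_values`` may be an ``(n, 3)`` array matching ``plane.voxels``
    or a full ``(nx, ny, nz, 3)`` field from which the plane voxels are
    gathered.  The sign follows the plane normal orientation.
    """
    if plane.n_voxels == 0:
        raise ValueError("degenerate plane")
    vals = np.asarray(field_values, dtype=float)
    if vals.ndim == 2 and vals.shape == (plane.n_voxels, 3):
        f = vals
    elif vals.ndim == 4 and vals.shape[-1] == 3:
        i, j, k = plane.voxels.T
        f = vals[i, j, k]
    else:
        raise ValueError(
            "field_values must be (n_plane_voxels, 3) or a full (nx, ny, nz, 3) field"
        )
    if not np.all(np.isfinite(f)):
        raise ValueError("field undefined (non-finite) on plane voxels")
    return float(grid.dS(plane.normal) * (f @ plane.normal).sum())


def to_mmHg(dp_pa):
    """Convert pressure from Pa to mmHg (1 mmHg = 133.322 Pa)."""
    return np.asarray(dp_pa, dtype=float) / MMHG_PA


def midpoint_field(v_t, v_t1) -> np.ndarray:
    """Field at the temporal midpoint: (v_t + v_{t+1}) / 2, voxelwise."""
    a = np.asarray(v_t, dtype=float)
    b = np.asarray(v_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)
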