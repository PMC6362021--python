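"""Synthetic 4D flow phantoms with closed-form ground-truth relative pressure.

Straight-tube flows with analytic solutions take the place of the
patient-specific CFD anatomies a scanner study would use: every
downstream module (segmentation, virtual-field solve, estimators,
metrics) is testable against the Hagen-Poiseuille law and the Womersley
oscillatory-flow solution without any external data.  A truncated-
Gaussian noise model parameterized by image SNR and the velocity
encoding emulates phase-contrast MRI noise.

Ground-truth conventions: traces are p_inlet - p_outlet over the tube
length in Pa, sampled at frame midpoints, matching every estimator's
output convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .core import (
    EXTERIOR,
    INTERIOR,
    INLET,
    OUTLET,
    WALL,
    DomainLabels,
    FluidProperties,
    Plane,
    RelativePressureTrace,
    VelocityField4D,
    VoxelGrid,
)

__all__ = [
    "TubeGeometry",
    "NoiseModel",
    "poiseuille_field",
    "womersley_field",
    "womersley_profile",
    "apply_noise",
    "sample_resolution",
    "tube_labels",
    "hagen_poiseuille_dp",
    "plane_separation",
]


@dataclass(frozen=True)
class TubeGeometry:
    """Straight rigid tube: radius, length (m), axis direction, optional stenosis.

    ``stenosis`` is ``(center_fraction, severity, width)``: a smooth
    Gaussian radius reduction ``R(s) = R*(1 - severity*exp(-(s-s_c)^2/(2*width^2)))``
    centered at ``center_fraction * length`` along the tube.  The
    stenotic velocity model is an approximate quasi-1D scaling used only
    for segmentation and plane-selection fixtures; it carries no
    ground-truth pressure claim.
    """

    radius: float
    length: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center: tuple[float, float, float] | None = None
    stenosis: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        a = np.asarray(self.axis, dtype=float)
        if np.linalg.norm(a) == 0:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", tuple(a / np.linalg.norm(a)))
        if self.stenosis is not None:
            frac, sev, width = self.stenosis
            if not (0 <= sev < 1):
                raise ValueError("stenosis severity must be in [0, 1)")
            if width <= 0:
                raise ValueError("stenosis width must be positive")

    def frame_coords(self, grid: VoxelGrid):
        """Axial coordinate s in [0, L] and radial distance r for each voxel."""
        ii, jj, kk = np.meshgrid(*grid.axes(), indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1)
        center = (
            np.asarray(self.center)
            if self.center is not None
            else np.asarray(grid.origin)
            + 0.5 * (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
        )
        a = np.asarray(self.axis)
        rel = pts - center
        s = rel @ a + 0.5 * self.length  # s=0 at tube start
        radial = rel - np.multiply.outer(rel @ a, a)
        r = np.sqrt((radial**2).sum(axis=-1))
        return s, r

    def local_radius(self, s):
        """Tube radius at axial position s (constant unless stenosed)."""
        R = np.full_like(np.asarray(s, dtype=float), self.radius)
        if self.stenosis is not None:
            frac, sev, width = self.stenosis
            sc = frac * self.length
            R = self.radius * (1.0 - sev * np.exp(-((s - sc) ** 2) / (2 * width**2)))
        return R


@dataclass(frozen=True)
class NoiseModel:
    """Truncated-Gaussian velocity noise parameterized by image SNR.

    The Gaussian standard deviation follows sigma_v = sqrt(2)*vmax/(pi*SNR)
    where ``vmax`` is the maximum velocity magnitude of the dataset
    (standing in for the velocity encoding).  Draws beyond
    ``truncation`` standard deviations are rejected and resampled, so
    ``sigma_v`` is the pre-truncation Gaussian parameter; the empirical
    SD of the truncated draws is ~0.8796*sigma_v for the +-2 sigma cut.
    """

    snr: float
    vmax: float
    seed: int = 0
    truncation: float = 2.0
    mode: str = "resample"  # or "clip"

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive (use np.inf for no noise)")
        if self.vmax < 0:
            raise ValueError("vmax must be non-negative")
        if self.mode not in ("resample", "clip"):
            raise ValueError("mode must be 'resample' or 'clip'")

    @property
    def sigma_v(self) -> float:
        if np.isinf(self.snr):
            return 0.0
        return float(np.sqrt(2.0) * self.vmax / (np.pi * self.snr))


def hagen_poiseuille_dp(mu: float, length: float, Q: float, radius: float) -> float:
    """Closed-form pressure drop 8*mu*L*Q/(pi*R^4) for steady laminar tube flow."""
    return 8.0 * mu * length * Q / (np.pi * radius**4)


def _check_lumen(geom: TubeGeometry, grid: VoxelGrid):
    a = np.abs(np.asarray(geom.axis))
    # transverse spacings: those not along the main axis direction
    order = np.argsort(a)
    h_t = max(grid.spacing[order[0]], grid.spacing[order[1]])
    if 2 * geom.radius < 2 * h_t:
        raise ValueError(
            f"unresolvable lumen: diameter {2*geom.radius:.4g} m spans fewer than "
            f"2 voxels at {h_t:.4g} m spacing"
        )


def poiseuille_field(
    geom: TubeGeometry,
    peak_velocity: float,
    grid: VoxelGrid,
    frames: int = 2,
    dt: float = 0.05,
    fluid: FluidProperties | None = None,
) -> tuple[VelocityField4D, RelativePressureTrace]:
    """Steady parabolic tube flow plus its Hagen-Poiseuille ground truth.

    The axial profile is ``v(r) = v_peak * (1 - r^2/R^2)`` inside the
    lumen and zero outside, constant over ``frames`` time samples.  The
    returned truth trace is the pressure drop over the full tube length
    ``geom.length`` at frame midpoints (constant in time).
    """
    fluid = fluid or FluidProperties()
    _check_lumen(geom, grid)
    s, r = geom.frame_coords(grid)
    if geom.stenosis is None:
        inside = (r < geom.radius) & (s >= 0) & (s <= geom.length)
        profile = np.where(inside, peak_velocity * (1.0 - (r / geom.radius) ** 2), 0.0)
    else:
        # mass-conserving quasi-1D scaling: mean velocity scales with 1/area
        Rs = geom.local_radius(s)
        inside = (r < Rs) & (s >= 0) & (s <= geom.length)
        vp = peak_velocity * (geom.radius / Rs) ** 2
        profile = np.where(inside, vp * (1.0 - (r / Rs) ** 2), 0.0)
    a = np.asarray(geom.axis)
    v3 = profile[..., None] * a
    values = np.broadcast_to(v3, (frames,) + v3.shape).copy()
    field = VelocityField4D(grid=grid, dt=dt, values=values)
    Q = np.pi * geom.radius**2 * peak_velocity / 2.0
    dp = hagen_poiseuille_dp(fluid.mu, geom.length, Q, geom.radius)
    t_mid = dt * (np.arange(frames - 1) + 0.5)
    truth = RelativePressureTrace(t_mid, np.full(frames - 1, dp))
    return field, truth


def womersley_profile(r, t, radius, grad_amplitude, omega, rho, mu):
    """Axial velocity of oscillatory tube flow (Womersley solution).

    Driving pressure gradient: ``-dp/dz = G cos(omega t)`` with
    ``G = grad_amplitude`` (Pa/m).  Returns the axial velocity at radial
    positions ``r`` (may be an array) and time(s) ``t``.
    """
    alpha = radius * np.sqrt(omega * rho / mu)
    i32 = 1j**1.5
    denom = jv(0, i32 * alpha)
    rr = np.asarray(r, dtype=float) / radius
    shape_fac = 1.0 - jv(0, i32 * alpha * rr) / denom
    V = grad_amplitude / (1j * omega * rho) * shape_fac
    t = np.asarray(t, dtype=float)
    return np.real(np.multiply.outer(np.exp(1j * omega * t), V)).squeeze()


def womersley_field(
    geom: TubeGeometry,
    pressure_gradient_amplitude: float,
    period: float,
    grid: VoxelGrid,
    frames: int,
    fluid: FluidProperties | None = None,
) -> tuple[VelocityField4D, RelativePressureTrace]:
    """Pulsatile tube flow from the classical Womersley solution.

    Velocity is evaluated at frame times ``t_n = n * T / frames`` over
    one period; the ground truth is ``dp(t) = L * G * cos(omega t)``
    (inlet minus outlet over the full tube length) at frame midpoints.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if frames < 8:
        raise ValueError("womersley phantom requires at least 8 frames")
    fluid = fluid or FluidProperties()
    _check_lumen(geom, grid)
    omega = 2.0 * np.pi / period
    dt = period / frames
    s, r = geom.frame_coords(grid)
    inside = (r < geom.radius) & (s >= 0) & (s <= geom.length)
    times = dt * np.arange(frames)
    # profile for all (t, voxel) at once
    prof = womersley_profile(
        r.ravel(), times, geom.radius, pressure_gradient_amplitude, omega,
        fluid.rho, fluid.mu,
    )
    prof = prof.reshape((frames,) + r.shape)
    prof = np.where(inside[None, ...], prof, 0.0)
    a = np.asarray(geom.axis)
    values = prof[..., None] * a
    field = VelocityField4D(grid=grid, dt=dt, values=values)
    t_mid = dt * (np.arange(frames - 1) + 0.5)
    dp = geom.length * pressure_gradient_amplitude * np.cos(omega * t_mid)
    return field, RelativePressureTrace(t_mid, dp)


def apply_noise(field: VelocityField4D, model: NoiseModel) -> VelocityField4D:
    """Add truncated-Gaussian noise, i.i.d. per component/voxel/frame.

    Deterministic for a fixed ``model.seed``.  Draws beyond
    ``truncation * sigma_v`` are rejection-resampled (or clipped when
    ``model.mode == 'clip'``).  With infinite SNR the field is returned
    unchanged (as a copy).
    """
    vmax_data = field.vmax
    if model.vmax < vmax_data - 1e-12:
        raise ValueError(
            f"noise model vmax {model.vmax:.4g} below dataset maximum velocity "
            f"{vmax_data:.4g}"
        )
    sigma = model.sigma_v
    if sigma == 0.0:
        return VelocityField4D(field.grid, field.dt, field.values.copy())
    rng = np.random.default_rng(model.seed)
    noise = rng.normal(0.0, sigma, size=field.values.shape)
    bound = model.truncation * sigma
    if model.mode == "clip":
        np.clip(noise, -bound, bound, out=noise)
    else:
        bad = np.abs(noise) > bound
        while bad.any():
            noise[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
            bad = np.abs(noise) > bound
    return VelocityField4D(field.grid, field.dt, field.values + noise)


def sample_resolution(
    field: VelocityField4D, new_spacing: float, new_frames: int
) -> VelocityField4D:
    """Downsample a field in space (box averaging) and time (linear).

    ``new_spacing`` must be an integer multiple of the (isotropic)
    source spacing; ``new_frames`` must not exceed the source frame
    count.  Used to build resolution/SNR sweep grids.
    """
    h = field.grid.spacing
    if not np.allclose(h, h[0]):
        raise ValueError("sample_resolution requires isotropic source spacing")
    if new_spacing < h[0] - 1e-12:
        raise ValueError("upsampling requested: new spacing below source spacing")
    f = new_spacing / h[0]
    fi = int(round(f))
    if abs(f - fi) > 1e-9:
        raise ValueError(
            f"new spacing must be an integer multiple of source spacing "
            f"(requested factor {f:.4g})"
        )
    if new_frames > field.frames:
        raise ValueError("upsampling requested: more frames than source")
    if new_frames < 2:
        raise ValueError("need at least 2 frames")
    v = field.values
    if fi > 1:
        nx, ny, nz = field.grid.shape
        cx, cy, cz = (nx // fi) * fi, (ny // fi) * fi, (nz // fi) * fi
        v = v[:, :cx, :cy, :cz, :]
        nt = v.shape[0]
        v = v.reshape(nt, cx // fi, fi, cy // fi, fi, cz // fi, fi, 3).mean(
            axis=(2, 4, 6)
        )
        origin = tuple(
            field.grid.origin[a] + 0.5 * (fi - 1) * h[a] for a in range(3)
        )
        grid = VoxelGrid(v.shape[1:4], (new_spacing,) * 3, origin)
    else:
        grid = field.grid
    if new_frames < field.frames:
        t_old = field.dt * np.arange(field.frames)
        t_new = np.linspace(0.0, t_old[-1], new_frames)
        out = np.empty((new_frames,) + v.shape[1:])
        idx = np.searchsorted(t_old, t_new, side="right") - 1
        idx = np.clip(idx, 0, field.frames - 2)
        wgt = (t_new - t_old[idx]) / field.dt
        for m in range(new_frames):
            out[m] = (1 - wgt[m]) * v[idx[m]] + wgt[m] * v[idx[m] + 1]
        v = out
        dt = t_new[1] - t_new[0]
    else:
        dt = field.dt
    return VelocityField4D(grid, dt, v)


def plane_separation(inlet: Plane, outlet: Plane, grid: VoxelGrid) -> float:
    """Axial distance between the centroids of two planes (m)."""
    pi = grid.positions(inlet.voxels).mean(axis=0)
    po = grid.positions(outlet.voxels).mean(axis=0)
    return float(abs((po - pi) @ outlet.normal))


def tube_labels(
    geom: TubeGeometry,
    grid: VoxelGrid,
    inlet_slice: int | None = None,
    outlet_slice: int | None = None,
) -> tuple[DomainLabels, Plane, Plane]:
    """Geometric domain labelling of an axis-aligned tube phantom.

    Builds interior/inlet/outlet/wall labels directly from the known
    geometry (no segmentation involved) with end planes at the first and
    last lumen slices along the tube axis, or at explicit slice indices.
    The inlet normal points outward (against the axis), the outlet
    normal along it.
    """
    a = np.asarray(geom.axis)
    ax = int(np.argmax(np.abs(a)))
    if not np.isclose(abs(a[ax]), 1.0):
        raise ValueError("tube_labels requires an axis-aligned tube")
    sign = 1.0 if a[ax] > 0 else -1.0
    s, r = geom.frame_coords(grid)
    Rs = geom.local_radius(s)
    lumen = (r < Rs) & (s >= 0) & (s <= geom.length)
    if not lumen.any():
        raise ValueError("tube does not intersect the grid")
    ks = np.unique(np.nonzero(lumen)[ax])
    k_in = ks[0] if sign > 0 else ks[-1]
    k_out = ks[-1] if sign > 0 else ks[0]
    if inlet_slice is not None:
        k_in = inlet_slice
    if outlet_slice is not None:
        k_out = outlet_slice
    labels = np.full(grid.shape, EXTERIOR, dtype=np.int8)

    def ax_index(arr, k):
        sl = [slice(None)] * 3
        sl[ax] = k
        return arr[tuple(sl)]

    lo, hi = (k_in, k_out) if k_in < k_out else (k_out, k_in)
    between = np.zeros(grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[ax] = slice(lo + 1, hi)
    between[tuple(sl)] = True
    labels[lumen & between] = INTERIOR
    inl = np.zeros(grid.shape, dtype=bool)
    ax_index(inl, k_in)[...] = True
    out = np.zeros(grid.shape, dtype=bool)
    ax_index(out, k_out)[...] = True
    labels[lumen & inl] = INLET
    labels[lumen & out] = OUTLET
    # wall: non-lumen voxels 6-adjacent to the interior
    from scipy import ndimage

    fluid = labels > 0
    struct = ndimage.generate_binary_structure(3, 1)
    near = ndimage.binary_dilation(labels == INTERIOR, structure=struct) & ~fluid
    labels[near] = WALL
    inlet_vox = np.argwhere(labels == INLET)
    outlet_vox = np.argwhere(labels == OUTLET)
    n_axis = np.zeros(3)
    n_axis[ax] = -sign
    inlet_plane = Plane(inlet_vox, n_axis, role="inlet")
    outlet_plane = Plane(outlet_vox, -n_axis, role="outlet")
    return DomainLabels(grid, labels), inlet_plane, outlet_plane
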