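"""Relative-pressure estimators: virtual work-energy and comparators.

The flagship estimator projects the Navier-Stokes momentum balance of
the measured field v onto the virtual field w and reads the relative
pressure off the resulting power balance at each time midpoint:

    dp * Q + dKe/dt + Ae + Ve = 0,

where Ke is the virtual kinetic energy, Ae the virtual advective power,
Ve the virtual viscous dissipation rate and Q the virtual flow through
the inlet plane (the w.n-weighted hydraulic-power normalization; it
equals minus the outlet virtual flux by incompressibility).  With
w = -n on the inlet and flow running inlet to outlet, Q < 0 and
dp = p_inlet - p_outlet > 0 for a forward Poiseuille flow.  The
boundary shear power is neglected: with w normal to the end planes it
scales with axial flow-gradient variations, which are small in a
resolved vascular segment.

Comparators: the classic work-energy estimator that uses the measured
field itself as the test field (degenerates as its own flow Q -> 0),
the simplified Bernoulli (advective term only, single-point plane
velocities) and the unsteady Bernoulli (advective + inertial line
integral along the centreline).

All estimators follow a statsmodels-like shape: a model object built
from the data, whose ``fit()`` returns a results object carrying the
pressure trace, the per-midpoint energy decomposition and diagnostics,
with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DomainLabels,
    FluidProperties,
    Plane,
    RelativePressureTrace,
    VelocityField4D,
    flow_rate,
    midpoint_field,
    to_mmHg,
)
from .smoothing import (
    FilterParams,
    SavitzkyGolay3D,
    calibrate_filter,
    gradient_w,
    temporal_derivative,
)
from .virtual_field import (
    StokesSolverConfig,
    VirtualField,
    _pool,
    solve_stokes,
    virtual_flow,
)

__all__ = [
    "EnergyDecomposition",
    "energy_terms",
    "VwerpModel",
    "VwerpResults",
    "WerpModel",
    "WerpResults",
    "BernoulliModel",
    "UnsteadyBernoulliModel",
    "TraceResults",
    "vwerp",
    "werp",
    "bernoulli",
    "unsteady_bernoulli",
]


@dataclass
class EnergyDecomposition:
    """Per-midpoint virtual work-energy terms and the resulting pressure.

    ``q`` is the inlet-side (hydraulic-power) flow, so the bookkeeping
    identity ``dp_pa * q + dke_dt + ae + ve = 0`` holds exactly at every
    valid midpoint.  ``q_outlet`` is the outlet-plane flux of the test
    field (equal to ``-q`` up to solver tolerance for the virtual
    field).  ``valid`` flags midpoints where the flow normalization was
    non-degenerate.
    """

    times: np.ndarray
    ke: np.ndarray
    dke_dt: np.ndarray
    ae: np.ndarray
    ve: np.ndarray
    q: np.ndarray
    q_outlet: np.ndarray
    dp_pa: np.ndarray
    valid: np.ndarray

    def residual(self) -> np.ndarray:
        """Energy-identity residual dp*q + dKe/dt + Ae + Ve (W); ~0 by construction."""
        return self.dp_pa * self.q + self.dke_dt + self.ae + self.ve

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "ke": self.ke,
                "dke_dt": self.dke_dt,
                "ae": self.ae,
                "ve": self.ve,
                "q": self.q,
                "q_outlet": self.q_outlet,
                "dp_pa": self.dp_pa,
                "dp_mmhg": to_mmHg(self.dp_pa),
                "valid": self.valid,
            }
        )


def energy_terms(
    v_mid: np.ndarray,
    dvdt: np.ndarray,
    Gv: np.ndarray,
    w: np.ndarray,
    Gw: np.ndarray,
    labels: DomainLabels,
    inlet: Plane,
    outlet: Plane,
    fluid: FluidProperties,
    Gw_adv: np.ndarray | None = None,
) -> dict:
    """Discretized virtual work-energy terms for one time midpoint.

    Volume sums run over the interior voxels of the measurement grid
    (the voxelized region of interest); surface sums over the inlet and
    outlet plane voxels with their outward normals.  ``w``/``Gw`` are
    the test field and its gradient on the same grid.

    ``Gw_adv`` optionally supplies a different test-field gradient for
    the advective volume term: with the flux-form (staggered) gradient
    there, the volume sum telescopes exactly against the end-plane
    surface sums, so the advective power of a fully developed flow
    cancels to round-off instead of leaving an inlet-development
    residual.  ``Gw`` itself enters the viscous term, paired with the
    polynomial-fit velocity gradient.
    """
    if Gv is None:
        raise ValueError("missing velocity gradient (order-0 filter cannot supply one)")
    if Gw_adv is None:
        Gw_adv = Gw
    grid = labels.grid
    dV = grid.dV
    interior = labels.interior
    vm = v_mid[interior]
    wm = w[interior]
    ke = fluid.rho * dV * float(np.einsum("nc,nc->", vm, wm))
    dke = fluid.rho * dV * float(np.einsum("nc,nc->", dvdt[interior], wm))
    surf = 0.0
    for plane in (inlet, outlet):
        i, j, k = plane.voxels.T
        vv = v_mid[i, j, k]
        ww = w[i, j, k]
        vn = vv @ plane.normal
        surf += grid.dS(plane.normal) * float(np.einsum("nc,nc,n->", vv, ww, vn))
    vol_adv = dV * float(np.einsum("na,nab,nb->", vm, Gw_adv[interior], vm))
    ae = fluid.rho * (surf - vol_adv)
    ve = fluid.mu * dV * float(np.einsum("nab,nab->", Gv[interior], Gw[interior]))
    return {"ke": ke, "dke_dt": dke, "ae": ae, "ve": ve}


def _max_gradient(field: VelocityField4D, mask: np.ndarray) -> float:
    """Max spatial-gradient magnitude of the peak-systole frame (1/s)."""
    speeds = field.speed()
    mean_speed = speeds[:, mask].mean(axis=1) if mask.any() else speeds.mean((1, 2, 3))
    peak = int(np.argmax(mean_speed))
    g = 0.0
    for c in range(3):
        for b, gb in enumerate(np.gradient(field.values[peak, ..., c], *field.grid.spacing)):
            g = max(g, float(np.abs(gb[mask]).max()) if mask.any() else 0.0)
    return g if g > 0 else 1.0


def _resolve_filter(field, mask, filter_params, snr, seed, min_order):
    if isinstance(filter_params, FilterParams):
        return filter_params
    if filter_params in (None, "auto"):
        if filter_params == "auto" and snr is not None:
            mg = _max_gradient(field, mask)
            vmax = max(field.vmax, 1e-12)
            return calibrate_filter(
                min(field.grid.spacing), mg, snr, seed=seed, vmax=vmax,
                min_order=min_order,
            )
        # minimal-smoothing default: quadratic fit over 3^3 kernels is
        # exact for locally parabolic profiles and supplies gradients
        return FilterParams(2, 3)
    raise ValueError("filter_params must be FilterParams, 'auto' or None")


class _ResultsBase:
    """Common surface of all estimator results objects."""

    method = "base"

    def __init__(self, trace: RelativePressureTrace, diagnostics: dict):
        self.trace = trace
        self.diagnostics = diagnostics

    @property
    def dp_pa(self) -> np.ndarray:
        return self.trace.dp_pa

    @property
    def dp_mmhg(self) -> np.ndarray:
        return self.trace.dp_mmhg

    def to_dataframe(self) -> pd.DataFrame:
        return self.trace.to_dataframe()

    def save_trace(self, path) -> None:
        self.trace.to_csv(path)

    def plot(self, ax=None, **kwargs):
        """Plot the relative-pressure trace in mmHg."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.times, self.trace.dp_mmhg,
                label=kwargs.pop("label", self.method), **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"$\Delta p$ (mmHg)")
        ax.legend()
        return ax

    def summary(self) -> str:
        dp = self.trace.dp_pa
        finite = dp[np.isfinite(dp)]
        lines = [
            f"{'Relative pressure estimate':^64}",
            "=" * 64,
            f"method:           {self.method}",
            f"midpoints:        {len(self.trace)}",
        ]
        if finite.size:
            lines += [
                f"peak dp:          {np.max(finite):.4g} Pa "
                f"({to_mmHg(np.max(finite)):.4g} mmHg)",
                f"mean dp:          {np.mean(finite):.4g} Pa",
            ]
        for k, v in self.diagnostics.items():
            if np.isscalar(v):
                lines.append(f"{k + ':':<18}{v}")
        lines.append("=" * 64)
        return "\n".join(lines)


class TraceResults(_ResultsBase):
    """Results carrying only a pressure trace (Bernoulli-family)."""

    def __init__(self, trace, diagnostics, method):
        super().__init__(trace, diagnostics)
        self.method = method


class VwerpResults(_ResultsBase):
    """Virtual work-energy estimate with its full energy decomposition."""

    method = "vwerp"

    def __init__(self, trace, energy, virtual_field, filter_params, diagnostics):
        super().__init__(trace, diagnostics)
        self.energy = energy
        self.virtual_field = virtual_field
        self.filter_params = filter_params

    def to_dataframe(self) -> pd.DataFrame:
        return self.energy.to_dataframe()


class WerpResults(VwerpResults):
    method = "werp"

    def __init__(self, trace, energy, filter_params, diagnostics):
        _ResultsBase.__init__(self, trace, diagnostics)
        self.energy = energy
        self.virtual_field = None
        self.filter_params = filter_params


class VwerpModel:
    """Relative pressure from the virtual work-energy balance.

    Parameters
    ----------
    field : VelocityField4D
        Measured velocity image (SI units).
    labels : DomainLabels
        Interior/inlet/outlet/wall labelling of the measurement grid.
    inlet, outlet : Plane
        End planes with outward normals.
    fluid : FluidProperties, optional
        Density and viscosity (defaults: blood).
    filter_params : FilterParams, "auto" or None
        Spatial noise filter; "auto" calibrates on a matched 1D sinusoid
        (requires ``snr``); None uses the minimal-smoothing quadratic
        default.  Order >= 1 is required since the filter also supplies
        velocity gradients.
    solver_config : StokesSolverConfig, optional
        Virtual-field solver settings (subsampling, tolerance).
    virtual_field : VirtualField, optional
        Reuse a previously solved virtual field (it only depends on the
        domain, not on the velocity data).
    q_epsilon_frac : float
        Degeneracy guard: |Q| must exceed this fraction of the inlet area.
    """

    def __init__(
        self,
        field: VelocityField4D,
        labels: DomainLabels,
        inlet: Plane,
        outlet: Plane,
        fluid: FluidProperties | None = None,
        filter_params=None,
        solver_config: StokesSolverConfig | None = None,
        snr: float | None = None,
        virtual_field: VirtualField | None = None,
        q_epsilon_frac: float = 1e-3,
        calibration_seed: int = 0,
    ):
        if field.frames < 2:
            raise ValueError("at least 2 frames are required")
        self.field = field
        self.labels = labels
        self.inlet = inlet
        self.outlet = outlet
        self.fluid = fluid or FluidProperties()
        self.solver_config = solver_config or StokesSolverConfig()
        self.snr = snr
        self._vf = virtual_field
        self.q_epsilon_frac = q_epsilon_frac
        self.filter_params = _resolve_filter(
            field, labels.fluid, filter_params, snr, calibration_seed, min_order=1
        )
        if self.filter_params.order < 1:
            raise ValueError("vwerp requires a filter of order >= 1 for gradients")

    def solve_virtual_field(self) -> VirtualField:
        if self._vf is None:
            self._vf = solve_stokes(
                self.labels, self.solver_config, inlet_normal=self.inlet.normal
            )
        return self._vf

    def fit(self) -> VwerpResults:
        vf = self.solve_virtual_field()
        sub_lab = vf.labels.labels
        w_grid = _pool(vf.w, sub_lab, self.labels)
        Gw_grid = _pool(gradient_w(vf, scheme="node"), sub_lab, self.labels)
        if vf.faces is not None:
            Gw_adv = _pool(gradient_w(vf, scheme="mac"), sub_lab, self.labels)
        else:
            Gw_adv = Gw_grid
        q_in = virtual_flow(vf, self.inlet)
        q_out = virtual_flow(vf, self.outlet)
        inlet_area = self.inlet.n_voxels * self.labels.grid.dS(self.inlet.normal)
        eps = self.q_epsilon_frac * inlet_area
        if abs(q_in) < eps:
            raise ValueError(
                f"degenerate virtual flow: |Q| = {abs(q_in):.3e} < {eps:.3e}"
            )
        sgop = SavitzkyGolay3D(
            self.labels.fluid, self.labels.grid.spacing, self.filter_params
        )
        N = self.field.frames
        t_mid = self.field.dt * (np.arange(N - 1) + 0.5)
        cols = {k: np.zeros(N - 1) for k in ("ke", "dke_dt", "ae", "ve")}
        dp = np.zeros(N - 1)
        for n in range(N - 1):
            vm = midpoint_field(self.field.values[n], self.field.values[n + 1])
            dv = temporal_derivative(self.field, n)
            vm_f = sgop.filter_vector(vm)
            dv_f = sgop.filter_vector(dv)
            Gv = sgop.gradient_tensor(vm)
            terms = energy_terms(
                vm_f, dv_f, Gv, w_grid, Gw_grid, self.labels,
                self.inlet, self.outlet, self.fluid, Gw_adv=Gw_adv,
            )
            for k in cols:
                cols[k][n] = terms[k]
            total = terms["dke_dt"] + terms["ae"] + terms["ve"]
            if not np.isfinite(total):
                bad = [k for k in ("dke_dt", "ae", "ve") if not np.isfinite(terms[k])]
                raise FloatingPointError(
                    f"non-finite energy term(s) {bad} at midpoint {n}"
                )
            dp[n] = -total / q_in
        energy = EnergyDecomposition(
            times=t_mid, ke=cols["ke"], dke_dt=cols["dke_dt"], ae=cols["ae"],
            ve=cols["ve"], q=np.full(N - 1, q_in), q_outlet=np.full(N - 1, q_out),
            dp_pa=dp, valid=np.ones(N - 1, dtype=bool),
        )
        diagnostics = {
            "q_inlet": q_in,
            "q_outlet": q_out,
            "flux_imbalance_rel": abs(q_in + q_out) / max(abs(q_out), 1e-300),
            "sg_fallback_voxels": sgop.n_fallback,
            **{f"stokes_{k}": v for k, v in vf.diagnostics.items()
               if np.isscalar(v)},
        }
        trace = RelativePressureTrace(t_mid, dp)
        return VwerpResults(trace, energy, vf, self.filter_params, diagnostics)


class WerpModel:
    """Classic work-energy estimator: the measured field is its own test field.

    Identical power-balance bookkeeping, but w := v (the filtered
    midpoint field) and Q is the measured flow through the inlet plane
    at each midpoint, so the estimate degenerates when the net flow
    vanishes; such midpoints are flagged invalid (NaN) rather than
    reported as divergent numbers.
    """

    def __init__(
        self,
        field: VelocityField4D,
        labels: DomainLabels,
        inlet: Plane,
        outlet: Plane,
        fluid: FluidProperties | None = None,
        filter_params=None,
        snr: float | None = None,
        q_epsilon_frac: float = 1e-3,
        calibration_seed: int = 0,
    ):
        if field.frames < 2:
            raise ValueError("at least 2 frames are required")
        self.field = field
        self.labels = labels
        self.inlet = inlet
        self.outlet = outlet
        self.fluid = fluid or FluidProperties()
        self.q_epsilon_frac = q_epsilon_frac
        self.filter_params = _resolve_filter(
            field, labels.fluid, filter_params, snr, calibration_seed, min_order=1
        )

    def fit(self) -> WerpResults:
        grid = self.labels.grid
        sgop = SavitzkyGolay3D(self.labels.fluid, grid.spacing, self.filter_params)
        N = self.field.frames
        t_mid = self.field.dt * (np.arange(N - 1) + 0.5)
        inlet_area = self.inlet.n_voxels * grid.dS(self.inlet.normal)
        vchar = max(self.field.vmax, 1e-300)
        eps = self.q_epsilon_frac * inlet_area * vchar
        cols = {k: np.zeros(N - 1) for k in ("ke", "dke_dt", "ae", "ve")}
        q_arr = np.zeros(N - 1)
        qo_arr = np.zeros(N - 1)
        dp = np.full(N - 1, np.nan)
        valid = np.zeros(N - 1, dtype=bool)
        for n in range(N - 1):
            vm = midpoint_field(self.field.values[n], self.field.values[n + 1])
            dv = temporal_derivative(self.field, n)
            vm_f = sgop.filter_vector(vm)
            dv_f = sgop.filter_vector(dv)
            Gv = sgop.gradient_tensor(vm)
            terms = energy_terms(
                vm_f, dv_f, Gv, vm_f, Gv, self.labels,
                self.inlet, self.outlet, self.fluid,
            )
            for k in cols:
                cols[k][n] = terms[k]
            q = flow_rate(vm_f, self.inlet, grid)
            q_arr[n] = q
            qo_arr[n] = flow_rate(vm_f, self.outlet, grid)
            if abs(q) < eps:
                warnings.warn(
                    f"werp: near-zero flow |Q|={abs(q):.3e} m^3/s at midpoint {n}; "
                    "estimate flagged invalid",
                    stacklevel=2,
                )
                continue
            dp[n] = -(terms["dke_dt"] + terms["ae"] + terms["ve"]) / q
            valid[n] = True
        energy = EnergyDecomposition(
            times=t_mid, ke=cols["ke"], dke_dt=cols["dke_dt"], ae=cols["ae"],
            ve=cols["ve"], q=q_arr, q_outlet=qo_arr, dp_pa=dp, valid=valid,
        )
        diagnostics = {
            "n_invalid": int((~valid).sum()),
            "q_epsilon": eps,
        }
        return WerpResults(
            RelativePressureTrace(t_mid, dp), energy, self.filter_params, diagnostics
        )


def bernoulli(v1: float, v2: float, fluid: FluidProperties | None = None) -> float:
    """Simplified Bernoulli pressure drop 0.5*rho*(v1^2 - v2^2) in Pa.

    In the plane-to-plane convention of this package, ``v1`` is the
    single-point speed on the *outlet* plane and ``v2`` on the *inlet*
    plane, which makes the result p_inlet - p_outlet (positive across an
    accelerating stenosis).
    """
    fluid = fluid or FluidProperties()
    if not (np.isfinite(v1) and np.isfinite(v2)):
        raise ValueError("speeds must be finite")
    return 0.5 * fluid.rho * (v1**2 - v2**2)


class BernoulliModel:
    """Simplified Bernoulli from single-point plane velocities.

    ``point='max'`` picks the maximum-speed voxel on each plane
    (mimicking Doppler peak-velocity practice); ``point='mean'`` uses
    the plane-mean speed.
    """

    def __init__(self, field, inlet: Plane, outlet: Plane,
                 fluid: FluidProperties | None = None, point: str = "max"):
        if point not in ("max", "mean"):
            raise ValueError("point must be 'max' or 'mean'")
        self.field = field
        self.inlet = inlet
        self.outlet = outlet
        self.fluid = fluid or FluidProperties()
        self.point = point

    def _plane_speed(self, vm, plane):
        i, j, k = plane.voxels.T
        s = np.sqrt((vm[i, j, k] ** 2).sum(axis=1))
        return float(s.max() if self.point == "max" else s.mean())

    def fit(self) -> TraceResults:
        N = self.field.frames
        t_mid = self.field.dt * (np.arange(N - 1) + 0.5)
        dp = np.zeros(N - 1)
        for n in range(N - 1):
            vm = midpoint_field(self.field.values[n], self.field.values[n + 1])
            v_in = self._plane_speed(vm, self.inlet)
            v_out = self._plane_speed(vm, self.outlet)
            dp[n] = bernoulli(v_out, v_in, self.fluid)
        return TraceResults(
            RelativePressureTrace(t_mid, dp), {"point": self.point}, "bernoulli"
        )


class UnsteadyBernoulliModel:
    """Bernoulli plus the inertial line integral along the centreline.

    dp = 0.5*rho*(v_out^2 - v_in^2) + rho * int_inlet^outlet (dv/dt).ds,
    with the temporal derivative taken between frames (midpoint rule in
    time, trapezoid rule along the path).  The path stands in for the
    trace of a particle advected through the segment.
    """

    def __init__(self, field, centerline, fluid: FluidProperties | None = None):
        cl = np.atleast_2d(np.asarray(centerline, dtype=int))
        if cl.shape[0] < 2:
            raise ValueError("centerline must contain at least 2 points")
        self.field = field
        self.centerline = cl
        self.fluid = fluid or FluidProperties()

    def fit(self) -> TraceResults:
        N = self.field.frames
        t_mid = self.field.dt * (np.arange(N - 1) + 0.5)
        grid = self.field.grid
        pos = grid.positions(self.centerline)
        dseg = np.diff(pos, axis=0)  # (m-1, 3)
        i, j, k = self.centerline.T
        dp = np.zeros(N - 1)
        rho = self.fluid.rho
        for n in range(N - 1):
            vm = midpoint_field(self.field.values[n], self.field.values[n + 1])
            dv = temporal_derivative(self.field, n)
            dv_path = dv[i, j, k]  # (m, 3)
            integ = 0.5 * ((dv_path[:-1] + dv_path[1:]) * dseg).sum()
            v_path = vm[i, j, k]
            v_in = float(np.linalg.norm(v_path[0]))
            v_out = float(np.linalg.norm(v_path[-1]))
            dp[n] = 0.5 * rho * (v_out**2 - v_in**2) + rho * integ
        return TraceResults(
            RelativePressureTrace(t_mid, dp),
            {"path_points": self.centerline.shape[0]},
            "unsteady_bernoulli",
        )


# ---------------------------------------------------------------------------
# functional wrappers


def vwerp(field, labels, inlet, outlet, fluid=None, filter_params=None,
          solver_config=None, **kw):
    """One-call virtual work-energy estimate: (trace, energy decomposition)."""
    res = VwerpModel(field, labels, inlet, outlet, fluid=fluid,
                     filter_params=filter_params, solver_config=solver_config,
                     **kw).fit()
    return res.trace, res.energy


def werp(field, labels, inlet, outlet, fluid=None, filter_params=None, **kw):
    """One-call classic work-energy estimate: pressure trace."""
    return WerpModel(field, labels, inlet, outlet, fluid=fluid,
                     filter_params=filter_params, **kw).fit().trace


def unsteady_bernoulli(field, centerline, fluid=None):
    """One-call unsteady Bernoulli estimate along a centreline path."""
    return UnsteadyBernoulliModel(field, centerline, fluid).fit().trace
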