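"""Construction of the divergence-free virtual field w by a Stokes solve.

The virtual field is the auxiliary test field that projects the
Navier-Stokes momentum balance onto the vascular segment of interest:
it must be solenoidal, vanish on the vessel wall and equal the inward
unit normal (-n) on the inlet plane.  Any field with these properties
gives the same relative pressure in exact arithmetic; here w is the
solution of the Stokes boundary-value problem

    lap(w) + grad(lambda) = 0,   div(w) = 0   in the interior,
    w = -n on the inlet,  w = 0 on the wall,
    zero pseudo-traction (dw/dn = 0, lambda = 0) on the outlet,

discretized with a MAC staggered finite-difference scheme on the
labeled voxel lattice: velocity components live on cell faces, the
Lagrange multiplier lambda at cell centers.  The adjoint-pair
gradient/divergence operators make the Schur complement G^T A^-1 G
symmetric positive definite, so the multiplier is found by conjugate
gradients; the three per-component momentum Laplacians are solved by a
sparse direct factorization (or ILU-preconditioned BiCGstab on large
refined lattices).  The discrete divergence of the returned field is
the quantity the iteration drives to the solver tolerance.

Wall and inlet boundary values are imposed exactly; the no-slip
condition for face components tangential to a boundary is enforced by
antisymmetric ghost values, placing the zero on the staircase surface
itself (second-order at flat boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, bicgstab, cg, spilu, splu

from .core import (
    EXTERIOR,
    INTERIOR,
    INLET,
    OUTLET,
    WALL,
    DomainLabels,
    Plane,
    VoxelGrid,
)

__all__ = [
    "StokesSolverConfig",
    "VirtualField",
    "subsample_labels",
    "solve_stokes",
    "virtual_flow",
    "pool_to_grid",
]

# face status codes
_WGHOST, _UNKNOWN, _VALUE, _COPY, _IGHOST = 0, 1, 2, 3, 4

#: above this per-component system size the momentum Laplacians are
#: solved by ILU-preconditioned BiCGstab instead of a direct factor
#: (3D direct fill-in grows superlinearly in memory).
_DIRECT_LIMIT = 80_000


class _MomentumSolver:
    """SPD momentum-block solver.

    Sparse direct LU below ``_DIRECT_LIMIT`` unknowns; above it,
    ILU-preconditioned BiCGstab (direct 3D fill-in grows superlinearly
    in memory).  Inner solves run essentially to machine precision so
    the outer pressure-Schur CG keeps its convergence guarantees;
    successive solves are warm-started from the previous solution.
    """

    def __init__(self, A, inner_rtol: float):
        self.n = A.shape[0]
        if self.n <= _DIRECT_LIMIT:
            self._lu = splu(A.tocsc())
            self._A = None
        else:
            self._A = A.tocsr()
            self._ilu = spilu(
                A.tocsc(), drop_tol=1e-5, fill_factor=12,
                permc_spec="MMD_AT_PLUS_A",
            )
            self._M = LinearOperator((self.n, self.n), matvec=self._ilu.solve)
            self._rtol = inner_rtol
            self._x0 = None

    def solve(self, b):
        if self._A is None:
            return self._lu.solve(b)
        x, info = bicgstab(
            self._A, b, M=self._M, x0=self._x0, rtol=self._rtol, atol=0.0,
            maxiter=2000,
        )
        res = np.linalg.norm(b - self._A @ x) / max(np.linalg.norm(b), 1e-300)
        if info != 0 and res > 100 * self._rtol:
            raise RuntimeError(
                f"momentum inner BiCGstab failed: relative residual {res:.2e}"
            )
        self._x0 = x
        return x


@dataclass(frozen=True)
class StokesSolverConfig:
    """Numerical parameters of the virtual-field solve.

    ``subsample_spacing`` is the target node spacing for the refined
    lattice the Stokes problem is solved on (None keeps the image
    resolution); the image-resolution labels are refined by the integer
    factor that reaches it.  ``tolerance`` is the relative residual at
    which the pressure-Schur conjugate-gradient iteration stops; the
    divergence contract of the returned field is stated relative to it.
    """

    subsample_spacing: float | None = 0.5e-3
    tolerance: float = 1e-10
    inner_tolerance: float = 1e-11
    max_iterations: int = 4000

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class VirtualField:
    """Solved virtual field w and multiplier lambda on the (sub)grid.

    ``w`` has shape ``(nx, ny, nz, 3)`` with w = -n exactly on inlet
    nodes and w = 0 exactly on wall (and exterior) nodes; ``lam`` is the
    Lagrange multiplier (zero outside the interior).  ``diagnostics``
    records the iteration count, residuals and discrete fluxes.
    """

    grid: VoxelGrid
    w: np.ndarray
    lam: np.ndarray
    labels: DomainLabels
    inlet_normal: np.ndarray
    diagnostics: dict = _dcfield(default_factory=dict)
    faces: dict | None = None  # staggered face values/status from the solve

    def scaled(self, c: float) -> "VirtualField":
        """Uniformly rescaled copy (c*w, c*lambda); used in invariance checks."""
        faces = None
        if self.faces is not None:
            faces = {
                "values": [c * f for f in self.faces["values"]],
                "status": self.faces["status"],
                "inlet_scale": c * self.faces["inlet_scale"],
            }
        return VirtualField(
            self.grid, c * self.w, c * self.lam, self.labels,
            self.inlet_normal, dict(self.diagnostics), faces,
        )


def subsample_labels(labels: DomainLabels, target_spacing: float) -> DomainLabels:
    """Refine a label volume so each voxel becomes f^3 nodes of its label.

    The refinement factor ``f = spacing / target_spacing`` must be a
    (common) integer for every axis.  Boundary slabs become f nodes
    thick; only the fluid-adjacent layer enters the Stokes solve, so the
    thickness is harmless.
    """
    h = labels.grid.spacing
    facs = []
    for a in range(3):
        f = h[a] / target_spacing
        fi = int(round(f))
        if fi < 1 or abs(f - fi) > 1e-9 * max(1.0, f):
            raise ValueError(
                f"target spacing {target_spacing} is not an integer refinement of "
                f"source spacing {h[a]}"
            )
        facs.append(fi)
    if len(set(facs)) != 1:
        raise ValueError("anisotropic refinement factors are not supported")
    f = facs[0]
    if f == 1:
        return DomainLabels(labels.grid, labels.labels.copy())
    lab = labels.labels
    for a in range(3):
        lab = np.repeat(lab, f, axis=a)
    new_spacing = tuple(h[a] / f for a in range(3))
    origin = tuple(
        labels.grid.origin[a] - h[a] * (f - 1) / (2 * f) for a in range(3)
    )
    grid = VoxelGrid(lab.shape, new_spacing, origin)
    return DomainLabels(grid, lab)


def _infer_inlet_normal(lab: np.ndarray) -> np.ndarray:
    """Outward inlet normal from the mean inlet-to-interior face direction."""
    inward = np.zeros(3)
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        lc, ld = lab[tuple(lo)], lab[tuple(hi)]
        inward[a] += np.count_nonzero((lc == INLET) & (ld == INTERIOR))
        inward[a] -= np.count_nonzero((ld == INLET) & (lc == INTERIOR))
    nrm = np.linalg.norm(inward)
    if nrm == 0:
        raise ValueError("inlet is not adjacent to the interior")
    return -inward / nrm


def _face_geometry(lab: np.ndarray, inlet_normal: np.ndarray):
    """Classify all faces per axis and index the unknowns."""
    solid = (lab == EXTERIOR) | (lab == WALL)
    status, value, fidx = [], [], []
    n_unknown = []
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        lc, ld = lab[tuple(lo)], lab[tuple(hi)]
        sc, sd = solid[tuple(lo)], solid[tuple(hi)]
        ic, idd = lc == INTERIOR, ld == INTERIOR
        oc, od = lc == OUTLET, ld == OUTLET
        nc, nd = lc == INLET, ld == INLET
        unk = (ic & (idd | od)) | (idd & (ic | oc))
        val = ~unk & ((ic & (nd | sd)) | (idd & (nc | sc)))
        st = np.full(lc.shape, _WGHOST, dtype=np.int8)
        st[unk] = _UNKNOWN
        st[val] = _VALUE
        cp = (st == _WGHOST) & (oc | od)
        st[cp] = _COPY
        ig = (st == _WGHOST) & (nc | nd)
        st[ig] = _IGHOST
        v = np.zeros(lc.shape)
        v[val & (nc | nd)] = -inlet_normal[a]
        fi = np.full(lc.shape, -1, dtype=np.int64)
        nu = int(unk.sum())
        fi[unk] = np.arange(nu)
        status.append(st)
        value.append(v)
        fidx.append(fi)
        n_unknown.append(nu)
    return status, value, fidx, n_unknown


def _assemble_momentum(a, status, value, fidx, h, inlet_normal):
    """Momentum Laplacian block, boundary RHS for face-component ``a``."""
    st_a, val_a, fi_a = status[a], value[a], fidx[a]
    unk = st_a == _UNKNOWN
    n = int(unk.sum())
    rows_idx = fi_a[unk]  # 0..n-1 in C-order of the face grid
    diag = np.zeros(n)
    rhs = np.zeros(n)
    inv_h2 = [1.0 / h[b] ** 2 for b in range(3)]
    coo_r, coo_c, coo_v = [], [], []
    for b in range(3):
        diag += 2.0 * inv_h2[b]
        for sgn in (-1, +1):
            # neighbor status/value/index arrays shifted by sgn along b,
            # sampled at the unknown-face positions
            pad = [(0, 0)] * 3
            pad[b] = (1, 1)
            pad_code = _COPY if b == a else _WGHOST
            st_p = np.pad(st_a, pad, constant_values=pad_code)
            val_p = np.pad(val_a, pad, constant_values=0.0)
            fi_p = np.pad(fi_a, pad, constant_values=-1)
            sl = [slice(None)] * 3
            sl[b] = slice(1 + sgn, st_a.shape[b] + 1 + sgn)
            st_n = st_p[tuple(sl)][unk]
            val_n = val_p[tuple(sl)][unk]
            fi_n = fi_p[tuple(sl)][unk]
            m = st_n == _UNKNOWN
            coo_r.append(rows_idx[m])
            coo_c.append(fi_n[m])
            coo_v.append(np.full(int(m.sum()), -inv_h2[b]))
            m = st_n == _VALUE
            np.add.at(rhs, rows_idx[m], val_n[m] * inv_h2[b])
            m = st_n == _COPY
            np.add.at(diag, rows_idx[m], -inv_h2[b])
            m = st_n == _WGHOST
            np.add.at(diag, rows_idx[m], +inv_h2[b])
            m = st_n == _IGHOST
            np.add.at(diag, rows_idx[m], +inv_h2[b])
            np.add.at(rhs, rows_idx[m], 2.0 * (-inlet_normal[a]) * inv_h2[b])
    coo_r.append(rows_idx)
    coo_c.append(rows_idx)
    coo_v.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(coo_v), (np.concatenate(coo_r), np.concatenate(coo_c))),
        shape=(n, n),
    ).tocsc()
    return A, rhs


def _assemble_gradient(lab, status, fidx, offsets, h, p_idx, n_p, n_u):
    """Sparse G mapping lambda (interior cells) to momentum rows."""
    coo_r, coo_c, coo_v = [], [], []
    for a in range(3):
        unk = status[a] == _UNKNOWN
        rows = fidx[a][unk] + offsets[a]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        pc = p_idx[tuple(lo)][unk]
        pd = p_idx[tuple(hi)][unk]
        inv_h = 1.0 / h[a]
        m = pc >= 0
        coo_r.append(rows[m])
        coo_c.append(pc[m])
        coo_v.append(np.full(int(m.sum()), -inv_h))
        m = pd >= 0
        coo_r.append(rows[m])
        coo_c.append(pd[m])
        coo_v.append(np.full(int(m.sum()), +inv_h))
    return sparse.coo_matrix(
        (np.concatenate(coo_v), (np.concatenate(coo_r), np.concatenate(coo_c))),
        shape=(n_u, n_p),
    ).tocsr()


def _continuity_rhs(lab, status, value, h, p_idx, n_p):
    """RHS of the continuity rows from Dirichlet face values."""
    bp = np.zeros(n_p)
    interior = lab == INTERIOR
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        # upper face of cell c: +value/h ; lower face: -value/h
        val = np.where(status[a] == _VALUE, value[a], 0.0)
        upper_cells = p_idx[tuple(lo)]
        m = interior[tuple(lo)] & (val != 0.0)
        np.add.at(bp, upper_cells[m], -val[m] / h[a])
        lower_cells = p_idx[tuple(hi)]
        m = interior[tuple(hi)] & (val != 0.0)
        np.add.at(bp, lower_cells[m], +val[m] / h[a])
    return bp


def solve_stokes(
    labels: DomainLabels,
    cfg: StokesSolverConfig | None = None,
    inlet_normal=None,
    rng_init: np.random.Generator | None = None,
) -> VirtualField:
    """Solve the Stokes boundary-value problem for the virtual field.

    ``labels`` may be at image resolution; if ``cfg.subsample_spacing``
    is set, the lattice is refined to (at most) that spacing first.  The
    inlet Dirichlet value is ``-inlet_normal`` (the outward plane
    normal); if not given it is inferred from the inlet/interior
    adjacency.  ``rng_init`` seeds the CG starting guess (zero by
    default) and exists to exercise solution uniqueness.
    """
    cfg = cfg or StokesSolverConfig()
    if cfg.subsample_spacing is not None:
        target = min(cfg.subsample_spacing, min(labels.grid.spacing))
        labels = subsample_labels(labels, target)
    lab = labels.labels
    grid = labels.grid
    h = grid.spacing
    if not (lab == INLET).any():
        raise ValueError("no inlet voxels labeled")
    if not (lab == INTERIOR).any():
        raise ValueError("no interior voxels labeled")
    if inlet_normal is None:
        inlet_normal = _infer_inlet_normal(lab)
    inlet_normal = np.asarray(inlet_normal, dtype=float)
    inlet_normal /= np.linalg.norm(inlet_normal)

    status, value, fidx, n_unknown = _face_geometry(lab, inlet_normal)
    n_u = int(sum(n_unknown))
    offsets = np.concatenate([[0], np.cumsum(n_unknown)])[:3]

    interior = lab == INTERIOR
    n_p = int(interior.sum())
    p_idx = np.full(lab.shape, -1, dtype=np.int64)
    p_idx[interior] = np.arange(n_p)

    # outflow possible?  some interior cell must see an outlet or an
    # outlet-adjacent unknown face chain; detect the direct adjacency.
    has_outlet = False
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        lc, ld = lab[tuple(lo)], lab[tuple(hi)]
        if (((lc == INTERIOR) & (ld == OUTLET)) | ((ld == INTERIOR) & (lc == OUTLET))).any():
            has_outlet = True
    if not has_outlet:
        raise ValueError("no outflow possible: outlet plane not adjacent to interior")

    bu = np.zeros(n_u)
    solvers = []
    for a in range(3):
        A, rhs = _assemble_momentum(a, status, value, fidx, h, inlet_normal)
        bu[offsets[a] : offsets[a] + n_unknown[a]] = rhs
        solvers.append(_MomentumSolver(A, cfg.inner_tolerance))

    G = _assemble_gradient(lab, status, fidx, offsets, h, p_idx, n_p, n_u)
    bp = _continuity_rhs(lab, status, value, h, p_idx, n_p)

    def a_solve(x):
        out = np.empty_like(x)
        for a in range(3):
            s = slice(offsets[a], offsets[a] + n_unknown[a])
            out[s] = solvers[a].solve(x[s])
        return out

    def schur_mv(p):
        return G.T @ a_solve(G @ p)

    S = LinearOperator((n_p, n_p), matvec=schur_mv)
    rhs_s = G.T @ a_solve(bu) + bp
    x0 = None
    if rng_init is not None:
        x0 = rng_init.standard_normal(n_p) * (abs(rhs_s).max() + 1.0)
    iters = [0]

    def cb(_):
        iters[0] += 1

    lam_vec, info = cg(
        S, rhs_s, x0=x0, rtol=cfg.tolerance, atol=0.0,
        maxiter=cfg.max_iterations, callback=cb,
    )
    res = rhs_s - schur_mv(lam_vec)
    rel = float(np.linalg.norm(res) / max(np.linalg.norm(rhs_s), 1e-300))
    if info > 0 and rel > 10 * cfg.tolerance:
        raise RuntimeError(
            f"Stokes pressure-Schur CG did not converge: relative residual "
            f"{rel:.3e} after {iters[0]} iterations (tolerance {cfg.tolerance:.1e})"
        )
    U = a_solve(bu - G @ lam_vec)

    # node-sampled field -------------------------------------------------
    w = np.zeros(lab.shape + (3,))
    lam = np.zeros(lab.shape)
    lam[interior] = lam_vec
    # face value arrays (unknowns + Dirichlet values) per axis
    fvals = []
    for a in range(3):
        fv = np.where(status[a] == _VALUE, value[a], 0.0)
        unk = status[a] == _UNKNOWN
        fv[unk] = U[offsets[a] + fidx[a][unk]]
        fvals.append(fv)
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        low_face = np.zeros(lab.shape)
        up_face = np.zeros(lab.shape)
        cnt_low = np.zeros(lab.shape)
        cnt_up = np.zeros(lab.shape)
        usable = np.isin(status[a], (_UNKNOWN, _VALUE))
        up_face[tuple(lo)] = np.where(usable, fvals[a], 0.0)
        cnt_up[tuple(lo)] = usable
        low_face[tuple(hi)] = np.where(usable, fvals[a], 0.0)
        cnt_low[tuple(hi)] = usable
        tot = cnt_low + cnt_up
        with np.errstate(invalid="ignore"):
            avg = np.where(tot > 0, (low_face + up_face) / np.maximum(tot, 1), 0.0)
        w[..., a] = np.where(interior, avg, 0.0)
    # inlet nodes: exact Dirichlet
    w[lab == INLET] = -inlet_normal
    # outlet nodes: copy the interior-adjacent face value (normal axis)
    # and the neighboring interior node value (tangential axes); deeper
    # slab layers inherit from already-assigned outlet neighbors.
    out_mask = lab == OUTLET
    assigned = ~out_mask  # everything else already final (wall/ext = 0)
    for _ in range(int(out_mask.sum()) + 1):
        todo = out_mask & ~assigned
        if not todo.any():
            break
        newly = np.zeros(lab.shape, dtype=bool)
        for a in range(3):
            for sgn in (-1, +1):
                nb_lab = np.full(lab.shape, -1, dtype=np.int8)
                nb_ass = np.zeros(lab.shape, dtype=bool)
                nb_w = np.zeros(lab.shape + (3,))
                src = [slice(None)] * 3
                dst = [slice(None)] * 3
                if sgn > 0:
                    src[a], dst[a] = slice(1, None), slice(0, -1)
                else:
                    src[a], dst[a] = slice(0, -1), slice(1, None)
                nb_lab[tuple(dst)] = lab[tuple(src)]
                nb_ass[tuple(dst)] = assigned[tuple(src)]
                nb_w[tuple(dst)] = w[tuple(src)]
                m = todo & (nb_lab == INTERIOR)
                if m.any():
                    # shared face value for the normal component: the face
                    # between cell k and k+1 sits at face-index k
                    fv = np.zeros(lab.shape)
                    sl = [slice(None)] * 3
                    sl[a] = slice(0, -1) if sgn > 0 else slice(1, None)
                    fv[tuple(sl)] = fvals[a]
                    w[m] = nb_w[m]
                    w[..., a][m] = fv[m]
                    newly |= m
                m2 = todo & ~newly & (nb_lab == OUTLET) & nb_ass
                if m2.any():
                    w[m2] = nb_w[m2]
                    newly |= m2
        if not newly.any():
            break
        assigned |= newly

    div_res = G.T @ U + bp
    wmax = float(np.abs(w).max()) or 1.0
    diag = {
        "cg_iterations": iters[0],
        "cg_relative_residual": rel,
        "div_max": float(np.abs(div_res).max()),
        "div_max_scaled": float(np.abs(div_res).max()) * min(h) / wmax,
        "n_pressure": n_p,
        "n_velocity": n_u,
        "refined_spacing": h,
    }
    doml = DomainLabels(grid, lab)
    faces = {"values": fvals, "status": status, "inlet_scale": 1.0}
    vf = VirtualField(grid, w, lam, doml, inlet_normal, diag, faces)
    diag["q_inlet"] = virtual_flow(vf, Plane(np.argwhere(lab == INLET), inlet_normal, role="inlet"))
    diag["q_outlet"] = virtual_flow(
        vf, Plane(np.argwhere(lab == OUTLET), -inlet_normal, role="outlet")
    )
    return vf


def virtual_flow(vf: VirtualField, plane: Plane, eps: float | None = None) -> float:
    """Virtual volumetric flow Q(w) = dS * sum(w . N) through a boundary plane.

    The sum runs over the single node layer of the plane's label that is
    6-adjacent to the interior (so thick subsampled slabs are not
    multi-counted); the sign follows the plane's outward normal.
    Raises when |Q| falls below ``eps`` (degenerate virtual flow).
    """
    lab = vf.labels.labels
    code = INLET if plane.role == "inlet" else OUTLET
    mask = lab == code
    if not mask.any():
        raise ValueError("degenerate plane: no voxels with the plane's label")
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)
    adj = ndimage.binary_dilation(lab == INTERIOR, structure=struct) & mask
    layer = adj if adj.any() else mask
    wn = vf.w[layer] @ plane.normal
    q = float(vf.grid.dS(plane.normal) * wn.sum())
    if eps is not None and abs(q) < eps:
        raise ValueError(f"degenerate virtual flow: |Q| = {abs(q):.3e} < {eps:.3e}")
    return q


def pool_to_grid(vf: VirtualField, target_labels: DomainLabels) -> np.ndarray:
    """Mean-pool the node-sampled w back to the measurement grid.

    Pooling averages over the f^3 sub-nodes of each measurement voxel,
    restricted to non-exterior sub-nodes so boundary voxels are not
    diluted by zeros from outside the domain.
    """
    return _pool(vf.w, vf.labels.labels, target_labels)


def _pool(arr: np.ndarray, sub_lab: np.ndarray, target_labels: DomainLabels) -> np.ndarray:
    shape = target_labels.grid.shape
    f = sub_lab.shape[0] // shape[0]
    if sub_lab.shape != tuple(s * f for s in shape):
        raise ValueError("subgrid shape is not an integer refinement of the target")
    if f == 1:
        return arr.copy()
    comp = arr.shape[3:] if arr.ndim > 3 else ()
    a = arr.reshape(shape[0], f, shape[1], f, shape[2], f, *comp)
    valid = (sub_lab != EXTERIOR).reshape(shape[0], f, shape[1], f, shape[2], f)
    vw = valid.astype(float)
    for _ in comp:
        vw = vw[..., None] * np.ones(1)
    num = (a * valid.reshape(shape[0], f, shape[1], f, shape[2], f, *([1] * len(comp)))).sum(
        axis=(1, 3, 5)
    )
    den = valid.sum(axis=(1, 3, 5)).astype(float)
    den = np.maximum(den, 1.0)
    for _ in comp:
        den = den[..., None]
    return num / den
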