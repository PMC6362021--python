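# Methods

## The estimation problem

Time-resolved phase-contrast MRI ("4D flow") measures the
three-component blood velocity `v(x, t)` on a uniform voxel grid, but
not the pressure. The clinically relevant quantity across a stenosis,
coarctation or dissected segment is the *relative pressure*
`Δp(t) = p_inlet(t) − p_outlet(t)` between two cross-sections. This
package estimates `Δp(t)` by projecting the Navier–Stokes momentum
balance of the measured field onto an auxiliary *virtual field* `w`:
multiplying the momentum equation by `w` and integrating over the
segment Ω gives the power balance

    dKe/dt + Ae + Ve + H(p) = 0,

with

* `Ke = ρ ∫ v·w dΩ` — virtual kinetic energy,
* `Ae = ρ ∮ (v·w)(v·n) dΓ − ρ ∫ v·∇w·v dΩ` — virtual advective power
  (surface minus volume form, using `∇·v = 0`),
* `Ve = μ ∫ ∇v : ∇w dΩ` — virtual viscous dissipation rate,
* `H(p) = ∮ p w·n dΓ` — virtual hydraulic power.

If `w` is divergence-free, vanishes on the vessel wall and equals the
inward unit normal `−n` on the inlet plane, then
`H(p) = Δp · Q` with `Q = ∫_Γi w·n dΓ` the (negative) inlet virtual
flux, and

    Δp = −(dKe/dt + Ae + Ve) / Q .

Any admissible `w` gives the same `Δp` in exact arithmetic; here `w` is
the unique solution of the Stokes boundary-value problem
`∇²w + ∇λ = 0`, `∇·w = 0` with `w = −n` on the inlet, `w = 0` on the
wall, and a traction-free outlet. The Lagrange multiplier `λ` enforces
incompressibility and has no physical-pressure meaning. The boundary
shear power is neglected: with `w` normal to the end planes it scales
with axial flow-gradient variation, small in a resolved segment; this
is an explicit modelling assumption.

Sign conventions: with `w = −n` on the inlet, `Q < 0` for any domain,
and `Δp > 0` means inlet pressure exceeds outlet pressure (forward
Poiseuille flow gives positive `Δp`). The energy decomposition stores
this inlet-side `Q`, so the bookkeeping identity
`Δp·Q + dKe/dt + Ae + Ve = 0` holds exactly at every reported midpoint
— it is the primary debugging surface of the method and is asserted in
the test suite.

## Discretization

**Time.** All quantities are evaluated at frame midpoints:
`v_{n+1/2} = (v_n + v_{n+1})/2` and
`∂v/∂t|_{n+1/2} = (v_{n+1} − v_n)/Δt` (second-order at the midpoint).
An N-frame dataset yields N−1 pressure samples.

**Space.** Volume sums run over the interior voxels of the labelled
region of interest with weight `dV`; surface sums over the inlet and
outlet plane voxels with weight `dS` and the outward plane normals.
Because the volume sums cover the interior region, the estimator
reports the pressure difference across the *bounding faces* of that
region: on a tube phantom the matched analytic reference uses the
interior axial extent (one voxel spacing shorter than the
plane-centroid separation; a 1–2 % bookkeeping difference at 1 mm
spacing on the test fixtures).

**Virtual field.** The Stokes problem is discretized with a MAC
staggered finite-difference scheme on the labelled voxel lattice:
velocity components on cell faces, `λ` at cell centers, 7-point
Laplacians, adjoint-pair gradient/divergence. Wall and inlet values
are imposed exactly on the Dirichlet faces; tangential no-slip uses
antisymmetric ghosts, placing the zero on the staircase surface
itself. The outlet condition is `λ = 0` with zero velocity gradient
(pseudo-traction-free); it also fixes the multiplier gauge, so no
mean-zero constraint is needed. The pressure Schur complement
`Gᵀ A⁻¹ G` is symmetric positive definite and solved by conjugate
gradients (relative tolerance 1e−10 by default); the three
per-component momentum Laplacians are factorized once — sparse LU up
to 80 000 unknowns per component, ILU-preconditioned BiCGstab above
(3-D direct fill-in grows superlinearly in memory). The discrete
divergence of the returned field equals the CG residual and is
reported in the diagnostics (`div_max_scaled`, the max-norm scaled by
node spacing over max |w|).

The lattice can be refined ("subsampled") to a target node spacing of
0.5 mm by integer voxel subdivision; refinement changes the tube-
phantom estimate by well under 1 %, so validation fixtures run at
image resolution and the 0.5 mm default is kept for production use.

**Test-field gradients.** Two finite-difference gradients of `w` are
used, each where it is the consistent choice:

* the *advective* volume term uses the solver-native flux-form
  gradient (diagonal entries are per-cell face-flux differences, so
  the tensor trace reproduces the discrete divergence and the volume
  sum telescopes exactly against the end-plane surface sums; the
  advective power of a fully developed flow then cancels to round-off
  instead of leaving an inlet-development residual);
* the *viscous* term pairs `∇v` from the polynomial fits (below) with
  plain central differences of the node-sampled `w` (half-spacing
  nonuniform stencils where a neighbour is wall/exterior, so the
  no-slip zero sits on the staircase boundary). The two gradients have
  matched smoothing bias near the wall, which is what makes the
  virtual-field estimate and the classic work-energy estimate agree on
  the Poiseuille oracle.

Both schemes are available through `gradient_w(vf, scheme=...)`.

**Measured-field gradients and denoising.** The velocity image is
filtered by mask-restricted 3-D Savitzky–Golay fits: a polynomial of
order k ∈ {0..3} least-squares fitted over cubic kernels of edge
{1,3,5,7,9} voxels, restricted to in-mask voxels (no zero padding —
that would bias the wall shear layer, exactly where the viscous
integrand peaks). The spatial gradient of `v` is the analytic gradient
of the same local fit. Where the in-mask neighbourhood leaves the fit
rank-deficient, gradients fall back to the highest full-rank order
(the least-norm fit still reproduces *values* of polynomial data
exactly, so filtering keeps the requested order). The (order, kernel)
pair is calibrated once per dataset by denoising a 1-D sinusoid with
the data's sampling, maximum spatial gradient, amplitude and SNR; ties
break toward lower order, then smaller kernel. The noise-free default
is (order 2, kernel 3): exact for locally parabolic profiles with
minimal smoothing.

## Domain labelling and segmentation

The lumen mask is built by thresholding the time-averaged speed image
at a user fraction (0.25–0.40) of the velocity encoding, deleting
6-connected islands of ≤ 10 voxels, filling enclosed cavities, keeping
the seed's component, and pruning border voxels that fail
temporal-derivative (±2 SD) or flow-direction (120°, 5-voxel
neighbourhood, optionally against a coarse Stokes reference flow)
consistency checks. The centreline is a minimum-cost path through the
inverse-cubed distance transform between the two end-cap centres
(located as principal-axis extreme-shell centroids; a plain BFS
diameter lands on cap corners). End planes cut the mask perpendicular
to the local centreline tangent at user seed points; the domain is
then labelled exterior/interior/inlet/outlet/wall, with the interior
the mask region bridging between (and excluding) the planes and the
wall the non-mask voxels 6-adjacent to it. Connectivity is
6-neighbourhood throughout; "peak systole" is the frame with maximum
spatial-mean speed.

## Phantoms and the noise model

Analytic tube flows with closed-form pressure drops substitute for
patient-specific CFD anatomies:

* **Steady Poiseuille**: `v(r) = v_peak (1 − r²/R²)`, ground truth
  `Δp = 8 μ L Q / (π R⁴)` with `Q = π R² v_peak / 2`.
* **Womersley flow**: the classical oscillatory solution for a
  sinusoidal axial pressure gradient in a rigid tube (Bessel-function
  radial profile), parameterized by the Womersley number
  `α = R √(ωρ/μ)`; truth `Δp(t) = L·G·cos(ωt)`. Validation uses α = 3
  — the oscillatory boundary-layer regime of large arteries — with the
  period following from α, R and the fluid constants.
* A quasi-1-D stenotic tube (Gaussian radius reduction, area-scaled
  velocity) exercises segmentation and plane selection only; it
  carries no pressure claim.

Default fluid constants are conventional blood values
(ρ = 1060 kg/m³, μ = 4.0 mPa·s), always overridable.

Image noise is zero-mean i.i.d. Gaussian per component/voxel/frame
with `σ_v = √2·v_max/(π·SNR)`, where `v_max` (maximum velocity
magnitude of the dataset) stands in for the velocity encoding; draws
beyond 2σ are rejection-resampled (clipping selectable), making the
empirical SD of the applied noise `≈ 0.8796 σ_v` (the ±2σ
truncated-normal moment). `σ_v` is the *pre-truncation* Gaussian
parameter. Noise is deterministic given the seed.

What the phantoms do **not** emulate: curved or branching anatomy,
partial-volume averaging at the wall, velocity aliasing, eddy-current
offsets, spatially correlated noise, or segmentation errors feeding
back into the domain (the validation fixtures hold the geometric
labelling fixed so the estimator, not the segmentation, is measured).
Passing the suite therefore demonstrates correctness of the estimation
machinery under controlled conditions, not clinical accuracy.

## Error metrics

Trace comparisons use a relative mean error
(`100·‖est − ref‖₂ / ‖ref‖₂`), an absolute RMS error (×100, input
units), and the relative error at the reference peak. Reference
samples are matched per estimate sample by the closest point in the
`(t, Δp)` plane within the window `(t_{n−1}, t_{n+1})`, with both axes
normalized to unit range so seconds and pascals are commensurate.

## Validation problem sizes and observed behaviour

The validation suite uses: an R = 8 mm, L = 80 mm tube at 1 mm voxels
(≈16 000 interior voxels) for the steady oracle; an R = 6 mm,
L = 40 mm tube, α = 3, 32 frames for the pulsatile oracle; and an
R = 8 mm, L = 48 mm pulsatile tube for the resolution (4→2→1 mm),
frame-count (8→16→32) and SNR (∞→30→10, 20 seeds per noise cell)
sweeps. Everything is regenerated from code at run time; there are no
stored datasets.

Known limitations: staircase voxelization of the wall bounds the
attainable accuracy at these resolutions (a few per cent on the tube
oracles, growing quickly below ~3 voxels per lumen radius); the
estimator degrades when the lumen is thin relative to the voxel size;
the classic work-energy comparator is undefined wherever its own net
flow vanishes (flagged, not extrapolated); and the centreline
heuristic assumes a roughly tubular, loop-free mask.
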