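# Methods

## Model overview

One well of a stirred 24-well plate is modelled as a closed cylinder of
culture medium (radius `R_w = 7.8 mm`, liquid height `H ≈ 10.5 mm` from
the 2-ml working volume) with a flat shear-free free surface, stirred at
ω ∈ {7, 13, 20} rad/s. The model has three layers: a steady axisymmetric
Stokes flow with swirl, a center-based particle model of the microtissue
population advected one-way by that flow, and a stress post-processor
that converts trajectories into per-microtissue von Mises doses.

### Flow

Because `Re_f = 4 ρ_f ω R_i²/μ_f < 2000` for every regime, inertia is
dropped entirely and the flow solves the incompressible Stokes equations.
The rotating impeller is replaced by an **actuator annulus** (inner
radius 1 mm, outer radius `R_i = 4 mm`, spanning z ∈ [5, 7] mm):

* the azimuthal momentum balance `∇²u_θ − u_θ/r² = 0` is solved with
  `u_θ = ωr` prescribed inside the annulus, no-slip walls, `u_θ = 0` on
  the axis and `∂u_θ/∂z = 0` at the free surface;
* the meridional flow solves the stream-function–vorticity system
  `E²ψ = rη`, `μ(∇²η − η/r²) = ∂f_z/∂r`, with ψ = 0 on all boundaries,
  Thom's no-slip closure for wall vorticity, η = 0 on the axis and free
  surface, driven by an axial body force `f_z` confined to the annulus.
  The force amplitude is calibrated so the upward flow through the
  actuator equals `Q = N_q ω R_i³` with pumping number `N_q = 0.4`
  (typical for a marine impeller). Because the problem is linear the
  calibration is one exact rescaling of the unit-amplitude solution.

At zero Reynolds number the two problems decouple; the swirl does not
drive a secondary meridional flow (that coupling is inertial). Both
systems are assembled with second-order centred differences on a uniform
(r, z) grid — default 64 × 96 nodes — and solved by sparse direct
factorization, so the solution is deterministic. Velocities recovered
from ψ satisfy the discrete continuity equation to machine precision.
Pressure is recovered from a Neumann Poisson problem driven by the body
force (the viscous wall term is neglected in its boundary condition);
it is written to output files but never used in stress evaluation, which
is purely deviatoric.

Nodal caches of the full cylindrical strain-rate tensor (including the
swirl couplings `E_rθ = ½(∂u_θ/∂r − u_θ/r)` and `E_θz = ½ ∂u_θ/∂z`), the
vorticity vector and the convective acceleration `(u·∇)u` are built once
per solve; all point queries interpolate these caches bilinearly, which
reproduces nodal values exactly and is exact for fields linear in r and z
(the analytic test fixtures).

Choice of geometry defaults: the device publishes no impeller drawing.
`R_i = 4 mm` is the largest centimetre-scale radius that keeps
`Re_f < 2000` at 20 rad/s; the 5-mm hub clearance places the blades near
mid-height, as a shaft-suspended impeller sits, and reproduces the
observed zone structure — a low-shear/stagnation region beneath the
impeller and a higher-shear region above it. With the actuator nearer the
floor the thin bottom gap becomes the *highest*-shear region, inverting
the observed structure; this fixed the clearance default.

### Particles

Each microtissue is a sphere of radius `R_p` (drawn from the size model
below) and density `ρ_p = ρ_f (1 + δ)`, default δ = 0.05. Per particle
the equation of motion contains:

* Stokes drag `6π μ_f R_p (u − v)` — valid since `Re_p ≈ 0.1 < 1`;
* the undisturbed-flow stress force `ρ_f V (Du/Dt)` (the
  pressure-gradient/Maxey–Riley term). This term is essential in a
  swirling flow: without it a neutrally buoyant particle cannot balance
  the centripetal acceleration and spuriously centrifuges outward at
  rate `t₀ω²r` instead of following streamlines;
* Saffman shear-gradient lift in McLaughlin vector form,
  `6.46 C μ_f R_p² (u−v)×ω_f / √(ν|ω_f|)`, with the Mei finite-Re
  correction `C(Re_slip, β)`, `β = R_p|ω_f|/|u−v|` clamped to [0, 1].
  Lift is a small fraction of drag at the slip velocities reached here;
  a toggle (`use_lift=False`) exists for sensitivity checks;
* buoyant weight `(ρ_p − ρ_f) V g` downward;
* linear spring–dashpot normal contacts between particles and with the
  walls: stiffness `k_n = 10⁻² N/m`, restitution-equivalent damping
  ratio 0.1, no tensile force. At the process volume fraction (~0.1%)
  contacts matter only inside the settled bottom layer
  (`use_contacts=False` toggles them off).

Added-mass, Basset-history and Magnus forces are omitted: with
`Stk ≈ 5·10⁻³` they are negligible against drag. One-way coupling only —
particles do not feed momentum back to the fluid.

Integration is semi-implicit Euler with the stiff drag term implicit in
the velocity update, then an explicit position update. The time step is
`dt = min(t₀_min/5, 0.2·Δx/(ωR_i))` (response time of the smallest
particle, and a fifth of a grid-cell crossing at tip speed) — about
2·10⁻⁴ s at default conditions. The inner loop is compiled with numba;
particle-pair contact detection uses a Verlet neighbour list with
displacement-triggered O(n²) rebuilds. Everything is float64 arithmetic
on preallocated arrays: runs are bitwise reproducible for a fixed seed,
and the global seed fans out to per-stage child seeds (sizes, placement)
via `numpy.random.SeedSequence`.

Discretization accuracy: the explicit position update drifts off a
circular streamline by `(ω dt)²/2` per step, i.e. percent-level phase and
radius error over a 60-s production run. This is irrelevant for
population stress statistics (it does not change which regions of the
flow a particle samples) but matters for trajectory-level oracles; the
convergence tests therefore integrate at resolved steps (10⁻⁵–10⁻⁶ s),
where the dynamics match independent 4th-order streamline integration to
well under 1% of the vessel radius over 10 s.

### Stress statistics

The dose assigned to a microtissue is the von Mises invariant
`σ_vM = √(1.5 τ:τ)` of the *fluid* deviatoric stress `τ = 2μ_f E`
interpolated at the particle centre, averaged over the trajectory with
trapezoidal time weighting. Contact stresses are excluded by default:
fluid stresses set the mPa scale of interest, and the contact law is a
numerical regularization rather than a tissue-mechanics model.

A particle is **stagnant** when, over the final half of its trajectory,
its mean height is below the impeller plane (the hub clearance) *and*
its mean speed is below 5% of the tip speed `ωR_i`; otherwise it is
recirculating. A stagnant population is **persistent** when it holds at
least 5% of the particles. Both thresholds are exposed as parameters.
The density sweep re-runs the suspension at each
δ ∈ {0, 0.02, …, 0.10} with a common seed and reports the stagnant
fraction per δ and the largest δ whose fraction reaches the persistence
threshold. In this model the stagnant fraction grows monotonically with
δ (heavier tissues settle, and nothing in a steady axisymmetric Stokes
flow resuspends a particle that has reached the floor), so the stagnant
population persists across the whole physiological density range
0–0.06 — and beyond it, which the sweep result flags as `beyond_range`.
Mechanisms that could break this monotonicity in the real device — blade
passage near the floor, inertial secondary flows, tissue–tissue
collisions at high local concentration — are outside a steady actuator
model.

### Synthetic microtissue sizes

Equivalent diameters are lognormal (positive support, mildly
right-skewed; the standard minimal model for aggregate sizes), specified
by a median and a coefficient of variation, with optional truncation on
circle-equivalent projected area `A = πd²/4`:

* **inoculum**: arithmetic mean 120 μm, CV 10% (a "homogeneous" nearly
  monomodal day-2 starting population; the 5th–95th percentile diameter
  ratio stays below 1.5);
* **steady state** (default for flow simulations, matching the fused
  post-inoculation population the stress characterization targets):
  median 160 μm, CV 25%, truncated by rejection to projected areas in
  [0.01, 0.04] mm² (diameters ≈ 113–226 μm). The median and CV are
  package choices — only the area range is observed — picked once to
  fill that range without piling mass at the truncation bounds.

`fit_size_spec` calibrates a spec to measured projected areas (plain
text, one value in mm² per line) by log-moment matching; sampling from a
fitted spec reproduces the input log-moments within sampling error, with
1/√n consistency. A volume-conserving fusion helper `d·k^(1/3)` supports
consistency checks (seven 120-μm tissues → ≈229 μm) but fusion kinetics
are deliberately not simulated: the steady-state distribution is taken
as given, not evolved.

## Desk-scale problem sizes

Production-style statistics in the tests and in `scripts/acceptance.py`
use a 64 × 96 flow grid, 300 microtissues, 60 s of simulated stirring
(≈3·10⁵ time steps) and trajectory sampling every 100 steps. These sizes
give seed-stable medians (≈ ±0.1 mPa between seeds at 13 rad/s) while a
regime run completes in ~10 s on one CPU. Unit-level oracles use coarser
32 × 48 grids and smaller populations.

## What the synthetic conditions do and do not show

The generator emulates the documented process conditions: geometry,
speeds, 2-ml volume, ~0.1% solids, the 120-μm inoculum and the
0.01–0.04 mm² steady-state size range. It does not emulate blade-resolved
flow, fusion/agglomeration kinetics, microtissue growth or deformation,
free-surface deflection, or inertial (finite-Re) corrections — the real
flow at `Re_f ≈ 10³` is laminar but not inertia-free, so quantitative
field-level agreement with a blade-resolved solver cannot be claimed.
Passing tests show that the *model as specified* reproduces the expected
dimensionless gates, analytic limits, scaling laws and the qualitative
zone structure, and that the stress distributions land in the expected
mPa bands; they are not evidence about any individual real bioreactor
well.

## Known limitations

* The actuator reduction has two free geometric parameters (hub radius,
  clearance) that are not published for the device; defaults are
  documented above and overridable in the config.
* The pressure field uses approximate Neumann boundary conditions and is
  diagnostic only.
* Wall contacts are frictionless: settled particles can slide along the
  floor under ambient shear but never roll or stick.
* The stagnant/recirculating split depends on two thresholds (5% tip
  speed, 5% persistence); both are exposed rather than fitted.
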