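# Methods

This note records the models, numerical choices and limitations behind
`spinaldrift`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Physical model

The carrier flow is an incompressible Newtonian fluid (CSF-like: density
ρ = 1000 kg/m³, kinematic viscosity ν = 0.7×10⁻⁶ m²/s) oscillating with
period T = 1 s through a rigid, axially periodic canal segment.  The solute
is passive (no buoyancy, no uptake) with molecular diffusivity
κ = 7×10⁻¹⁰ m²/s, i.e. Schmidt number ν/κ = 1000, typical of intrathecal
drugs.  Transport is computed two ways:

* **benchmark** — the oscillatory advection–diffusion equation with the
  time-periodic velocity v(x,t), resolving every cycle;
* **reduced model** — the same equation with the steady solenoidal mean
  Lagrangian velocity v_L(x) (or, for the comparison model from the
  literature, the cycle-averaged Eulerian velocity ⟨v⟩).

The governing small parameter is the dimensionless stroke length
ε = V_s/V_segment with V_s = ½∮|Q|dt.  The asymptotic streaming +
Stokes-drift formula for v_L is valid only for ε ≪ 1; at the physiological
ε = 0.439 the package measures v_L from one-cycle particle trajectories and
projects out the non-solenoidal remainder.

## Desk-scale geometry (what the generator emulates)

The study conditions emulate the cervical subarachnoid space with a 2-D
channel:

| parameter | value | rationale |
|---|---|---|
| channel gap H | 0.6 cm | annular-gap scale of the canal model |
| segment length L | 1.0 cm | intervertebral-scale repeating unit |
| segments tiled | 8 over x ∈ [1.6, 9.6] cm | the transport domain and bolus position reuse the canonical coordinates |
| grid | 32×64 per segment (256×64 transport) | resolves the oscillatory boundary layer δ = √(2ν/ω) ≈ 0.047 cm with ~5 cells |
| obstacles | two staggered cosine² wall bumps per segment, height 0.10 cm, half-width 0.3 cm | nerve-rootlet/ligament stand-ins whose spacing is comparable to the stroke length; smooth slopes keep transverse velocities within explicit stability limits on the stair-step mask |
| waveform | single-harmonic sinusoid, Q₀ chosen so ε = 0.439 | physiological stroke length; V_s ≈ 0.24 mL against the obstructed segment volume 0.54 mL |
| segment length vs L_seg | shortened to 1.0 cm | keeps the peak advective CFL of the physiological-ε flow (peak u ≈ 1.5πεL/T) below the explicit-scheme limit at the 256×64 resolution and the 0.005 s transport step |

The patent scenario removes the bumps but keeps the identical waveform, so
the isolated effect of the obstacles can be measured.  A small-stroke
variant scales the flow rate by 0.00763 (ε ≈ 0.00335) for asymptotic
validation.

What the 2-D generator does *not* emulate: the annular three-dimensional
cross-section and its azimuthal drift pathways, dura compliance, multiple
harmonics of the cardiac waveform, respiratory forcing, buoyancy and drug
uptake.  Passing tests therefore demonstrate the correctness and internal
consistency of the modeling chain under oscillatory flow with
obstacle-induced steady drift — not patient-specific accuracy.

## Flow solver

MAC staggered grid; fractional-step projection; conservative centred
advection with Adams–Bashforth-2 extrapolation; Crank–Nicolson viscous
terms (sparse LU, factorised once); compact 5-point pressure Poisson with
a pinned-cell gauge.  No-slip walls enter through mirror ghosts (wall at a
half cell) and Dirichlet face values on the stair-step mask.

The flow rate is imposed by a spatially uniform axial body force — the
surrogate for the inter-segment pressure difference — updated every step by
a PI controller whose gain is normalised by the precomputed one-step
flow-rate response of a unit force; the applied forcing is learned into a
per-phase feedforward table (integral action across cycles).  With the
default proportional gain of 1 the instantaneous flow-rate error is
cancelled to round-off (dead-beat) and the per-cycle error norm decreases
monotonically.  Convergence to the limit cycle is declared when the
cycle-to-cycle periodicity residual max|v(·,t) − v(·,t+T)|/max|v| drops
below 10⁻⁴ (typically 4–7 cycles; the bulk mode is controlled, so only
zero-net-flux viscous modes must decay).  The converged pressure surrogate
is reported in Pa; driving the same waveform through the obstructed canal
requires a ~19% larger forcing amplitude than the patent one.

Validation: against the exact oscillatory channel (Womersley) profile at
the physiological gap H = 0.3 cm (α ≈ 4.5) the worst per-phase relative L2
error is 0.5% at 64 transverse cells, and halving the spacing reduces the
error by factors 3.7–4 (second order).  At the H = 0.6 cm scenario gap
(α ≈ 9) the worst phase — flow reversal, where the profile norm is small —
reaches 1.6% at the same resolution; this reflects the thinner boundary
layer, not the scheme order.

## Lagrangian mean velocity

Particles seeded at every fluid-cell centre are advected for one cycle with
classical RK4 (substep = snapshot interval T/100), evaluating velocity by
tri-linear interpolation in (t, x, y): periodic-linear in time, bilinear in
space with a periodic ghost column and mirror-negated wall ghosts so the
interpolant vanishes on walls.  Manufactured (unbounded) fields instead use
linear extrapolation ghosts, since their walls are not physical.  A
particle whose position lands in a solid cell is truncated
(`entered_solid`) and excluded; on the obstructed scenario 98.6% of samples
complete the cycle.  The cycle-mean position x_o is the trapezoidal time
average of the unwrapped trajectory.  Twenty seeding phases (0.05 T apart)
are integrated; each (seed, phase) sample of v*_L = δx/T is deposited at
its own x_o by simplex-based linear interpolation (periodic tiling in x,
nearest-neighbour fallback flagged in metadata) and the per-phase grids are
averaged.  Whether x_o should also be phase-averaged before deposition is
ambiguous; depositing per phase and averaging on the grid was chosen as the
more local estimator.

Validation: on the traveling-wave fixture the trajectory-based, projected
v_L matches the asymptotic streaming+drift formula to 0.42% / 0.21% / 0.10%
at ε = 0.012/0.006/0.003 — first-order convergence in ε, with both routes
agreeing with the closed form U²k/(2ω).

## Helmholtz projection

Centre velocities are averaged to faces; solid and wall normal faces are
zeroed, which realises the Neumann condition ∂Φ/∂n = v*_L·n (equivalently
v_L·n = 0, restoring impermeability — the boundary condition is the
package's choice, with periodicity in x).  The compact 5-point Poisson
problem (zero-mean gauge, pure-Neumann nullspace pinned, direct sparse
solve with a 10⁻¹⁰ residual check) yields Φ; faces are corrected by its
face-normal gradient and averaged back to centres.  Because divergence,
gradient and Laplacian share the same face stencils the decomposition is
discretely orthogonal: ‖v_L‖₂ ≤ ‖v*_L‖₂ holds exactly, the face divergence
after projection is at round-off (kill ratio ~10⁻¹⁴), and projecting a
projected field is the identity (the face representation travels with the
field).  The reduced transport solver refuses fields that have not been
projected.

On the obstructed scenario at ε = 0.439 the non-solenoidal component is
small in the bulk (median 2.6% of the drift scale, relative L2 17%) but
reaches ~30% in a handful of obstacle-tip cells — genuine finite-stroke
particle convergence/divergence at stair-step corners (denser seeding and
alternative deposition do not reduce it).  The bulk statement is the tested
contract; the max-norm is reported, not asserted.

## Transport solvers

Both solvers share one conservative finite-volume core: unsplit explicit
flux-form update with flux-limited upwind reconstruction — the third-order
Koren limiter as the default for the oscillatory benchmark (the stand-in
for QUICK, which on coarse grids oscillates without limiting) and
second-order minmod for the reduced solver.  A dimension-split variant was
tried and rejected: next to stair-step obstacles the 1-D divergence of each
split component is large even though the field is solenoidal, and the split
scheme amplified the concentration field.  The unsplit update requires the
cellwise CFL sum |u|dt/dx + |v|dt/dy ≤ 1, which sets the benchmark step
dt = 0.005 s for the scenario (checked up front; violations raise
`StabilityError`).  Diffusion is explicit (diffusion number ≪ 1 at Schmidt
1000).  Velocity within a step is the linear-in-time blend of the two
bracketing phase snapshots at the step midpoint; advection uses the
solver's exactly divergence-free face velocities, so the interior update is
conservative to round-off.  Axial ends are outflow boundaries (first-order
donor extrapolation, zero-concentration inflow); exiting mass accumulates
in a ledger and the global balance closes to ~10⁻¹⁵ relative in all runs.
The reduced solver starts from dt = 1 s and shrinks it to the drift CFL
(~0.07 s on the obstructed scenario); with identical steady fields and
matched dt the two solvers agree to round-off.

Diagnostics follow the Taylor-dispersion picture: C(x,t) = ∫c ds per axial
station, centre of mass and variance by trapezoidal quadrature, and
κ_H(t) = [σ²(t) − σ²(0)]/(2t).

## Results and known limitations

At 60 cycles the reduced model reproduces the benchmark σ to 2.6%
(criterion: 5%); the Eulerian-mean comparison underpredicts σ by 34%; the
obstructed canal disperses 2.3× more than the patent one; and switching off
molecular diffusion changes the integrated profile by 0.4% — the dispersion
is kinematic, driven by the mean drift.

κ_H(t) of the obstructed benchmark rises toward a plateau but still changes
by 2.3% between 50 T and 60 T: in a steady 2-D drift field the streamlines
are integrable (no chaotic advection), so the early kinematic transient in
σ²(t) decays only as 1/t and has not fully vanished by 60 cycles.  This is
the main qualitative gap between the desk-scale analogue and a 3-D canal,
where azimuthal pathways randomise particle motion sooner.  The patent-run
κ_H is slightly negative (−4×10⁻⁴ cm²/s): with essentially no drift, the
limiter's small numerical contraction of the profile outweighs molecular
diffusion — a resolution statement, not a physical one.

Other limitations: stair-step (non-body-fitted) obstacle boundaries;
single-harmonic default waveform; 2-D only (the containers reserve an
optional third dimension but no operator implements it); rigid walls; no
injection-phase model.
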