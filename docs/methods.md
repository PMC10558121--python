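# Methods

## Model overview

`vesiflow` models size-based particle separation in a two-module
viscoelastic microfluidic device. The carrier fluid is a dilute 600-kDa PEO
solution in PBS; at the working concentrations (0.1–0.15% w/v) its shear
viscosity is rate-independent, so the velocity field is that of a Newtonian
fluid while elasticity enters only through the first normal stress
difference of the Oldroyd-B constitutive model,

    N1 = 2 * mu_p * lambda * gamma_dot**2 .

Particles are one-way coupled: the flow is solved without them, then each
particle feels an elastic lift proportional to the N1 gradient, Stokes drag,
and (optionally) inertial lift, virtual mass and buoyancy. Because elastic
lift scales as a³ and drag as a, lateral migration speed scales as a², which
is the entire separation principle: micron-scale species reach the
centerline within the first module while nanoscale species barely move off
the walls.

The device is represented as two straight channel modules joined by a
flux-split abstraction. Outlet junctions are not geometrically resolved;
each outlet is its flux fraction, and particles are routed by which side of
the dividing streamline (the streamline bounding that flux fraction) they
occupy at the module exit. This is exactly the information the separation
logic needs, and it sidesteps the unknown junction geometry.

## Fluid and particle parameters

| parameter | symbol | default | note |
|---|---|---|---|
| fluid density | rho_f | 1000 kg/m³ | aqueous buffer |
| total viscosity | eta | 1.43 mPa·s | mean of the two working PEO solutions |
| polymeric viscosity | mu_p | 0.41 mPa·s | Oldroyd-B polymer contribution |
| relaxation time | lambda | 0.55 ms | Oldroyd-B |
| elastic lift coefficient | C_e | 0.0184 | dimensionless |
| PEO coil gyration radius | r_g | 48 nm | sets D0 via Stokes–Einstein |
| solvent viscosity | eta_s | 1.0 mPa·s | water at room temperature |
| temperature | T | 293 K | "room temperature" is not further specified; 293 K with eta_s = 1.0 mPa·s reproduces the quoted D0 = 4.45e-12 m²/s within 1% |
| particle density | rho_p | 1050 kg/m³ | polystyrene; near-neutral buoyancy |
| channel width / height | w, H | 20 µm / 55 µm | per module |
| inlet rates | Q1/Q2/Q3 | 200/2000/3000 µl/h | sample + two guide streams |

A single effective viscosity is used throughout even though sample and guide
streams carry slightly different PEO concentrations; the dimensionless
analysis of the original design does the same, and two-fluid viscosity
stratification is out of scope. A concentration→viscosity lookup table is
provided with the single measured anchor pre-loaded; other concentrations
must be supplied explicitly.

The reported dimensionless numbers at the working point are R ≈ 25 and
R_P = R(a/w)² = 0.56 / 0.0625 / 0.0156 for 3 µm / 1 µm / 500 nm. The value
R_P = 0.006 sometimes quoted for 100-nm particles is inconsistent with
R(a/w)², which gives 6.25e-4 at R = 25; the package returns the formula
value and does not reproduce the quoted one. Likewise the formula value of
R is 25.7 with the stated inputs; the rounded 25 is accepted at 5% in tests.

## Flow solver

Steady incompressible 2D flow in each straight module is solved in
streamfunction–vorticity form on a uniform structured grid (default 41
lateral × 201 axial points): SOR sweeps on ∇²ψ = −ω interleaved with
red-black Gauss–Seidel sweeps on the steady vorticity transport equation,
first-order upwind convection (disabled in Stokes mode), Thom's formula for
wall vorticity, prescribed inflow profile (parabolic by default, plug
available) and zero-gradient outflow. Convergence is declared at a joint
dimensionless residual below 1e-8 (default), within a budget of 1e5 outer
iterations; non-convergence raises an error carrying the residual history.

Volumetric rates convert to depth-averaged 2D velocities through Q/(wH).
u_max is read from the solved field, never assumed. The streamfunction
doubles as the cumulative lateral flux, so dividing streamlines are roots of
a cubic-spline interpolant of ψ (not-a-knot, hence exact for the fully
developed cubic profile) found by Brent's method to ≲ 1e-12 m — comfortably
below the 1-nm requirement of the flux-split analysis. Pressure is
post-processed from the x-momentum balance and is diagnostic only.

At the first-order upwind discretization and R ≈ 25, Stokes and
Navier–Stokes solutions of the straight modules agree to < 2%, consistent
with fully developed flow being convection-free.

## Device plumbing and geometry calibration

Detailed junction dimensions of the original two-module design are not
available, so the default geometry is calibrated, not copied:

* **Plumbing.** All three inlets feed module 1 (total 5200 µl/h); the sample
  stream is pinched into two wall-adjacent bands jointly carrying 200/5200 of
  the flux. Module 2 carries only the module-1 side-outlet streams (48.3% of
  the total); a particle crossing between modules keeps its cumulative flux
  from the nearer sidewall (F₂(y′) = F₁(y)).
* **Outlet flux fractions.** Chosen so the dividing streamlines of the
  developed profile sit 6.4 µm from the sidewalls in module 1 (central waste
  fraction 51.67%) and 2.5 µm in module 2 (combined side fraction 8.59%),
  from the closed-form cumulative flux 3s² − 2s³ of the parabola.
* **Module lengths.** In a parabolic profile the overdamped lateral dynamics
  integrate in closed form: with η = 2(w/2 − d)/w the centerline offset,
  L = (G(η₀) − G(η₁)) u_max / k, G(η) = ln η − η²/2 and
  k = 256 C_e a² μ_p λ u_max² / (3π η_f w⁴). Each module length is the
  smallest value for which the largest class that must reach the centerline
  completes its migration (to within 5% of the half-width): the 3-µm class
  in module 1 starting from its wall clearance a/2, and the 1-µm class in
  module 2 starting from its flux-remapped module-1 exit position. This
  gives L₁ ≈ 0.28 mm and L₂ ≈ 3.6 mm at the default operating point
  (`default_geometry()` recomputes them for any fluid/flow configuration).

With these defaults the simulated routing reproduces the designed behavior:
3-µm particles to O₁, 1-µm and 500-nm to O₂, and roughly three quarters of
the 100-nm class to O₃ — the outermost part of the 100-nm entry band drifts
past the 2.5-µm dividing streamline within module 2 and is lost to O₂. That
loss fraction is an emergent prediction of the calibrated model, not a
fitted quantity.

## Particle dynamics

**Equation of motion.** Newton's second law with elastic lift, drag,
virtual mass and the optional inertial lift/buoyancy terms. Two deliberate
interpretations:

* *Elastic force sign.* Written literally as C_e a³ ∇N₁ with positive C_e,
  the force would point toward the high-shear walls, contradicting the
  observed centerline focusing; the package directs it toward decreasing N₁
  (an explicit sign convention in `ForceModelParams`, flippable for
  exploration).
* *Virtual mass.* The printed form ½ρ_f V_p (u − v_p) is dimensionally a
  mass×velocity; the standard relative-acceleration form
  ½ρ_f V_p (Du/Dt − dv_p/dt) is implemented, with the −dv_p/dt part folded
  into an effective mass (ρ_p + ½ρ_f)V_p.

Inertial lift has no published coefficient and is negligible at these
particle Reynolds numbers; it defaults to off but is available. Buoyancy is
zero for near-neutral particles and, in the planar model, acts normal to the
flow plane anyway; it is off by default.

**Stiffness and the overdamped default.** The velocity-relaxation times
(ρ_p + ½ρ_f) a² / (18 η) are 1e-10–1e-7 s against millisecond transits, so
the production integrator advances position only, with
v = u + C_e a² ∇N₁ / (3π η). The full stiff system is retained
(`mode="full_inertia"`) and agrees with the overdamped limit to < 1% of the
channel width on module-scale test problems; the terminal lateral velocity
matches the overdamped expression to < 0.1% on a frozen-gradient field.

**Integration.** Classical fixed-step RK4 on bilinearly interpolated
fields; the default step keeps the maximum displacement per step at or
below 0.2 grid cells, with a budget of 1e7 steps per particle (exceeding it
flags the trajectory as truncated; truncated particles count as lost). Wall
contact is handled by clamping to a clearance of a/2 with a flag — no wall
lift model is included. Entry positions are sampled uniformly in cumulative
flux within the sample bands from a seeded RNG. The per-particle inner loop
is JIT-compiled when `numba` is importable; the identical code runs un-jitted
otherwise.

**Outlet assignment.** Deterministic, by final lateral position against the
dividing streamlines; a particle exactly on a dividing streamline goes to
the wall-side outlet (documented tie-break).

## Separation metrics

Reconstructed from their usage in the field (their original formal
definitions are not available in text form):

* purity(outlet, class) = class count at outlet / total count at outlet;
* recovery(outlet, class) = class count at outlet / class input count
  (loss-including);
* separation efficiency(outlet, class) = class count at outlet / class count
  collected over all outlets (loss-excluding, hence ≥ recovery).

This reconstruction is consistent with the quoted benchmark percentages
(e.g. an efficiency of 97% coexisting with a recovery of 77% for the same
class and outlet). Degenerate denominators raise `MetricUndefinedError`
rather than returning NaN.

Gating operates in log10-intensity space with rectangular or convex
polygonal gates (shapely geometry underneath); gates must not overlap, so
assignment is single-valued and idempotent. NTA-style summaries use 5-nm
bins, the arithmetic mean, the modal bin center and the empirical cumulative
distribution, and rescale concentration by the dilution factor.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis assumes —
entry bands uniform in cumulative flux; multinomial class draws with
log-normal two-parameter intensity clouds (defaults: 9.7% sEV / 88.6% blood
cells / 1.7% other, clusters ≥ 6σ apart in log space); log-normal size
mixtures whose means are calibrated to 97 nm (sEV outlet) and 143 nm
(larger-EV outlet); whole-blood class concentrations (RBC 5e9, PLT 3e8,
WBC 7e6 per mL — physiological-typical stand-ins, not measured values) under
4:1 buffer dilution with a 5e8/mL sEV spike.

They deliberately do **not** emulate instrument physics (scatter models,
detector noise floors, swarm detection), particle–particle interactions,
vesicle deformability, or Brownian motion of the tracked particles (the
trajectory model is deterministic). Size-distribution shapes use a geometric
σ of 1.35 because only population means are constrained by the available
numbers; the dispersions are assumptions. Passing tests therefore validate
the model chain and its implementation, not the biology of real blood.

All generators are pure functions of (spec, seed); `simulate_device` and the
acceptance script derive every stream from one user seed.

## Numerical choices

* Flow residual tolerance 1e-8 (dimensionless, max-norm), iteration budget
  1e5; plug-inflow (developing-flow) test cases run at 1e-6.
* Gradients by second-order central differences, second-order one-sided at
  boundaries (`edge_order=2`) — exact for the parabolic profile.
* Dividing-streamline roots: Brent bisection, xtol 1e-12 m.
* RK4 step: ≤ 0.2 cells per step; full-inertia dt resolves the velocity
  relaxation time (0.02 τ).
* Ties on a dividing streamline route to the wall-side outlet; wall
  penetration clamps to a/2 and flags the trajectory.
* Default problem sizes (41×201 grids, 100–200 particles per class, 2e4
  synthetic events, 1e5 size draws) keep a full pipeline run in seconds to a
  couple of minutes on one CPU while leaving sampling error well inside the
  tolerances asserted in the tests.

## Known limitations

* 2D planar flow; no 3D lift maps, no expansion-region vortex structure.
  Outlet behavior is exactly as good as the flux-split abstraction.
* First-order upwind convection limits the solver's formal accuracy in
  developing-flow regions; the straight-module results are insensitive to
  this because fully developed flow has no convection.
* The elastic lift coefficient C_e is taken as a size- and
  position-independent constant; near-wall hydrodynamic interactions and
  shear-thinning are not modelled.
* Metric formulas are reconstructions (see above); purity of a simulated
  outlet can reach exactly 1 because the deterministic model has no
  contamination pathways other than mis-routing.
* The experimental benchmark percentages for blood-derived samples depend on
  physical blood and instrument effects and are outside what this model can
  or should reproduce; the package's claims are confined to the quantities
  its tests and acceptance script compute.
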