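# Methods

## Scope and reduction

The simulator reproduces the five-step protocol of an arterial clamping
experiment — homeostasis, clamp, healing, excision, wire myograph — on a
reduced thin-walled vessel instead of a 3D contact finite-element model.
The mouse thoracic aorta is a half cylinder (inner radius 0.325 mm, wall
0.04 mm, modeled axial slice 0.04 mm) carrying an `n_theta x n_r` grid
of material points.  The mixture deformation gradient is diagonal in the
local (radial, circumferential, axial) frame and fully incompressible;
volume change from mass turnover is neglected, so J = 1 always and the
deviatoric J^(-2/3) weights are identically one.  While pressurized the
wall is in plane strain axially (λ_z = 1) and satisfies the membrane
(Laplace) balance σ_θθ = p·r/h with σ_rr = 0, where r and h are the
deformed radius and thickness; the homeostatic target stress is
0.01 MPa · 0.325 mm / 0.04 mm = 0.08125 MPa.

What the reduction deliberately gives up: transmural stress gradients,
contact mechanics of the clamp (replaced by a calibrated injury profile,
below), bending-dominated shape changes (replaced by a small analytic
bending term in the myograph), and any spatial transport (agent
diffusion, SMC migration, endothelial regrowth fronts are all treated as
global or absent).

## Constitutive model

Elastin is Neo-Hookean with C10 = 0.04 MPa and a fixed deposition
stretch tensor G_elas = diag(1/(g_t·1.67), g_t, 1.67); the
circumferential entry g_t is the single unknown of the homeostatic
prestress solve.  Collagen consists of two symmetric dispersed fiber
families (k1 = 1.0 MPa, k2 = 1.5, κ = 0.1, α = π/8 from the
circumferential axis) laid down in daily cohorts; each cohort carries
the mixture deformation at its deposition and a fiber prestretch
g_coll = 1.1 (transverse 1/√g so det G_coll = 1).  No tension-only
switch is applied to the fibers: the stored energy is even in the strain
measure E and contributes in compression as well.  Contractile smooth
muscle adds (μ/2)(n3+n4)(Ī4 + u_rs − 1)² along the circumferential
direction, with μ = 0.42 MPa read as a μ/2 prefactor in the established
filament-sliding convention.

Stresses are evaluated analytically as σ_i = f_i ∂Ψ/∂f_i − p_lag with
the Lagrange pressure fixed by σ_rr = 0 (thin wall); a finite-difference
consistency test holds to better than 1e-5 relative on random admissible
states.

### Active tone in the pressure balance

Whether basal smooth-muscle tone participates in the homeostatic
pressure balance is a genuinely open design point.  We exclude it by
default (`active_in_balance=False`) and balance the pressure passively,
for a quantitative reason: with the given material constants the basal
active Cauchy stress (~0.13 MPa at the homeostatic crossbridge
population) alone exceeds the Laplace target (0.08125 MPa), so acute
loss of ~28% of contractile SMC would unload nearly half the wall stress
and drive a ~3% stretch deviation; the remodeling gains (K_pl = 4/day,
K_dd = 1.6/day, K_m = 26.64) then amplify this into runaway growth
(synthetic SMC ×50 within a month), far outside the observed healing
corridor.  With a passive balance the acute dilatation is set by the
collagen loss (~0.8% stretch deviation) and the month-scale trajectory
lands near the reported constituent changes.  The myograph always
includes the active response — vasoactive dosing is its purpose.  The
switch restores the alternative convention for sensitivity studies.

A consequence of the passive membrane balance is that the solved elastin
circumferential deposition stretch is below one (~0.92): the collagen
prestress (g_coll = 1.1 with k1 = 1 MPa) already overshoots the Laplace
target, so elastin must be deposited in circumferential compression to
balance it.  A transmurally resolved prestressing algorithm distributes
this differently; on a membrane there is only one balance to satisfy.
The homeostatic solver brackets g_t in [0.1, 2.5] and converges to a
residual below 1e-8 MPa.

## Clamp injury profile

The true overstretch field of a clamped artery comes from 3D contact
mechanics and concentrates at the luminal surface near the clamp edges.
We replace it by a deterministic parametric field of stretch-deviation
history β(θ, r̂) = peak · exp(−((θ−π/2)/width)²) · exp(−r̂/0.5): a
Gaussian ridge at the clamp-edge angle decaying through the wall.  The
deviation is tensile (λ_θθ = 1 + β) within a band around the edge and
compressive elsewhere — the flattened contact zone is compressed
circumferentially, and compressed fibers take no overload damage.

The three profile parameters are calibrated once per clamp load, in a
triangular (sequential, deterministic) order, to the acute post-clamp
survival fractions: the Gaussian width is slaved to the global
endothelial survival (the dead luminal arc is where β ≥ 0.38), the peak
to the grid-averaged contractile-SMC survival, and the tension-band
half-width to the overall collagen survival.  Everything downstream —
healing dynamics, myograph response — follows from the mechanics without
further fitting.  The calibration targets for 0.6 N are (0.3113, 0.7170,
0.9076) and for 1.27 N (0.2719, 0.7190, 0.9071); on a 48×3 grid the
calibrated profiles reproduce them to ±0.002 (endothelium, SMC) and
±0.003–0.02 (collagen, limited by the angular granularity of the band).

## Remodeling

Each step advances the tissue by Δt days (default 1):

1. solve the pressure equilibrium → Δλ = λ_θθ − 1 and, per cohort, the
   normalized fiber-stress deviation Δζ = (σ_f − σ_f,hom)/σ_f,hom (the
   fiber stress is the Cauchy stress resolved along the deformed fiber
   direction; normalizing makes Δζ dimensionless, consistent with its
   use in 1 + Δζ² and against the dimensionless damage constant 20);
2. decay all cohort survival fractions, deposit one new cohort per
   family at the current deformation with mass m₀·Γ·Δt, and prune
   cohorts below 1e-10 surviving mass;
3. exchange SMC phenotypes and apply synthetic proliferation;
4. heal the endothelium logistically and set inflammation to its
   complement.

The baseline production rate is not a free parameter: homeostatic
stationarity fixes m₀Δt = ρ₀(1 − exp(−K_qh Δt)) per family, which makes
the undamaged vessel an exact fixed point of the discrete turnover (the
test suite verifies < 1e-9 drift over 31 days).  Elastin is never
produced or degraded.  The contractile pool is capped by the relative
elastin available to grip and its growth by the synthetic cells
available (evaluated after their proliferation), keeping the exchange
exactly mass-conserving; contractile SMC are treated as a single pool
deposited at the homeostatic configuration.  New collagen deposition
happens only during healing steps, not while the clamp is held.

Two model variants alter single couplings: `no_redifferentiation`
freezes the contractile pool when Δλ < 0 (only inflammation-driven
proliferation remains), and `mech_independent_production` reduces the
production stimulus to Γ = ρ̂ˢˢᵐᶜ.  Run over 91 days, the original law
oscillates (collagen maximum near day 34, minimum near day 78), the
first variant damps the synthetic-cell swing by an order of magnitude,
and the second oscillates slightly more — the qualitative long-horizon
signatures the tests assert.

## Contractility

Kinetics run on seconds; remodeling on days; myograph stages are held to
steady state (quasi-static separation of scales).  The Hai–Murphy
four-state system is integrated with the exact matrix exponential
(unconditionally stable, conserves Σn to machine precision); steady
states are computed independently as the normalized nullspace of the
rate matrix, and the two routes agree to < 1e-8 on random rate sets.
Degenerate kinetics (no attachment path) fall back to the fully detached
state with a warning.

Filament sliding evolves viscously (η = 60 MPa·s) toward the
three-branch crossbridge stress balance; its stationary values have
closed forms at the lower (κ_c n₃) and upper (κ_c(n₃+n₄)) bounds, which
the integrator reproduces.  The ACh → endothelial NO release curve is a
saturating log-linear fit valid above 10^-8.2 M; it is clipped to zero
below that (outside the fitted measurement range, with a warning) and
scaled linearly by the intact endothelial fraction — the minimal
coupling consistent with "no endothelium, no ACh response".  Applied and
endothelium-derived NO add.

## Myograph

The excised ring (pressure and axial constraint released; recoil solved
from σ_θθ = σ_zz = 0 with basal tone) hangs on two rigid rods of radius
0.15 mm.  As the rod gap d opens, three zones follow: no contact while
the rod pair fits inside the circular ring; straightening of the circle
into a stadium at constant perimeter, resisted only by a small analytic
shell-bending force (EI = 6·C10·h³/12 per unit length — the only
mechanism the membrane model lacks and the one that sets the
low-stiffness middle zone); and stretching once the perimeter
2d + 2πr_rod exceeds the excised circumference.  Wall force per unit
axial length is the standard two-segment idealization F/L = 2σ_θθ·h_cur,
with the axial stretch solved from σ_zz = 0 at every gap.  The rod stops
at the preload 0.0133 N/mm; doses are then applied isometrically, each
dilator branching from the PE-constricted state as in separate myograph
runs.

## Numerical choices and problem sizes

- Root solves use Brent's method with near-machine tolerances
  (equilibrium residual < 1e-8 MPa enforced); the excision recoil uses a
  damped hybrid Newton with residual < 1e-7 MPa.
- Default scenario grid 48×3 (θ × radial); the endothelial survival
  count uses a fine 4000-point luminal trace, decoupled from the
  mechanical grid.  Tests and the acceptance script use coarser grids
  (2–16 angular points) where the state is uniform or only trends are
  asserted; the healing trajectory is grid-insensitive because the
  equilibrium stretch is a wall average.
- Time steps: 1 day (remodeling; halving it changes day-31 densities by
  ~2%), 0.01 s available for kinetic transients.
- Cohort pruning threshold 1e-10 of surviving mass (error < 1e-6 of
  total density over the simulated horizons).

## What the synthetic inputs do and do not show

The injury profile emulates only the segment-averaged acute damage
state; it does not reproduce the spatial pattern of a real clamp field,
so passing tests demonstrate the coupled damage–healing–contraction
laws under representative injuries, not contact mechanics.  Quantities
that depend on the 3D field — exact acute collagen/SMC maps, absolute
myograph forces — are checked qualitatively (orderings, zone structure,
variant contrasts), while the endothelium/inflammation trajectory,
elastin conservation and time-step convergence are checked numerically.

## Known limitations

No agent diffusion through the wall, no wall-shear-driven NO, no KCl
depolarization pathway, no SMC migration or localized re-endothelial-
ization, no viscoelasticity or opening-angle residual stress, no
frictional contact or lumen self-contact.  The forward-Euler remodeling
dynamics inherit the marginal stability of the underlying feedback
loops: long-horizon runs of the original variant oscillate, which is a
property of the model, not of the integrator (halving Δt does not
remove it).
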