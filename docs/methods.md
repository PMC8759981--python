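# Methods

`cordcool` simulates epidural cooling of the human spinal cord on a
two-dimensional axial cross-section of the trunk.  This note records the
model, its numerical treatment, the calibration choices, and what the
package's verification does and does not establish.

## Governing model

Tissue temperature obeys the Pennes bio-heat equation

    rho c dT/dt = div(k grad T) + w_b c_b (Ta - T) + q_m

where `rho c` is the volumetric heat capacity, `k` the thermal
conductivity, `q_m` a constant volumetric metabolic source, and the
perfusion term exchanges heat with arterial blood at temperature `Ta`
through the mass-perfusion rate `w_b` (kg s^-1 m^-3) and blood specific
heat `c_b`.  Ten material classes cover the cross-section (cord, CSF,
dura, epidural fat, yellow ligament, bone, muscle, viscera, subcutaneous
fat, catheter polymer); the catheter and the CSF carry neither metabolism
nor perfusion.  Two derived scales organise the physics:

* the perfusion decay length `lambda = sqrt(k/(w_b c_b))` — 6.8 mm in the
  cord, ~4 mm in the dura, ~15 mm in muscle — sets how far a boundary
  temperature disturbance penetrates perfused tissue at steady state;
* the perfusion time constant `tau = rho c/(w_b c_b)` — 360 s in the cord
  — sets how fast tissue relaxes back to the blood-defined equilibrium.

A consequence worth stating explicitly: away from boundaries every
perfused tissue equilibrates at `Ta + q_m/(w_b c_b)`, which for this
registry is `Ta + 0.24 .. 0.39` degC.  Deep-tissue temperature is pinned
by the blood, not by the skin, because the skin is many decay lengths
away.

Some sources print the perfusion term with an additional tissue-density
factor.  With a mass-perfusion rate in kg s^-1 m^-3 that extra factor is
dimensionally inconsistent, so the solver omits it; the variant remains
available (`calibration.extra_density_factor`) for sensitivity checks
only.

## Geometry

The anatomy is parametric: nested ellipses for cord (5 x 4 mm semi-axes),
CSF annulus (2.5 mm), dura (1 mm), epidural fat (3 mm) and ligament ring
(4 mm), enclosed by a vertebral arch and body, a ventral viscera ellipse,
muscle, a 10 mm subcutaneous band and a rounded-rectangle torso outline
(300 x 250 mm domain).  The catheter (outer radius 1.5 mm, lumen radius
1.0 mm) sits on the dorsal epidural midline, touching the dura.  These
dimensions are plausible adult thoracic values chosen once and exposed in
the configuration; no published dimensions back them, and they are the
largest single source of quantitative uncertainty.

Rasterization paints primitives back-to-front onto a square-cell grid;
cell-center inclusion decides membership.  Rasterized areas converge as
spacing x perimeter, so millimetre-thin annuli (dura, CSF) carry ~10%
area error at the 1 mm working resolution and reach the few-percent level
only below ~0.25 mm.

## Discretization

Finite volumes with the 5-point stencil; face conductances are harmonic
means of the adjoining cell conductivities, which keeps heat flux
continuous across material interfaces.  Verified behaviour: second-order
spatial convergence against manufactured solutions (observed order ~1.99)
and against the closed-form 1D perfused-slab profile (L_inf 0.0027 degC
at 0.25 mm); first-order temporal convergence of backward Euler (observed
order ~0.99).  Backward Euler is used for its unconditional stability and
monotonicity at tissue interfaces; at the working step of 0.5 s the
cord-center series moves by ~0.001 degC when the step is refined to
0.1 s, i.e. the time discretization is converged far below every other
error source.

Boundary closures:

* **Skin** — natural convection `q = h (T_s - T_amb)` into 30 degC
  ambient air with the laminar free-convection law
  `h = C dT^0.25`, C = 2.0 W m^-2 K^-1.25 by default.  The film
  coefficient is nonlinear; the stationary solver updates it by Picard
  iteration and transients freeze it at the phase-start field (skin
  temperature moves well under a degree per phase).  The half-cell
  conduction resistance is placed in series with the film.
* **Catheter, cooling phase** — lumen cells are Dirichlet at the coolant
  set-point.  Because the coolant is pumped and well mixed, lumen cells
  contribute no internal conduction resistance; the coolant-to-tissue
  face resistance is the catheter wall (0.5 mm of polymer, a sub-grid
  series resistance whenever the raster cannot resolve it) plus the
  remaining tissue gap measured from the actual lumen circle.  This
  immersed-boundary distance correction matters: the catheter is only
  1.5 cells in radius on the working grid, and without it the
  coarse-grid cooling is ~0.6 degC weak relative to a refined grid;
  with it the 1.0 mm / 0.5 mm / 0.25 mm steady cooled cord-center
  temperatures are 34.06 / 33.85 / 33.95 degC, i.e. a residual
  desk-resolution uncertainty of ~0.1-0.2 degC.
* **Catheter, after stoppage** — zero flux across the lumen surface
  (the stopped coolant column is treated as insulated); resolved
  catheter-wall cells keep conducting.
* **Domain edges** — adiabatic; the default anatomy never reaches them.
  Verification cases may impose fixed-value edge faces instead.

The stationary solve (pump off) is a direct sparse LU solve iterated on
the film coefficient to a relative residual of 1e-10 and provides the
t = 0 state of every protocol.  Transients reuse one LU factorization per
phase.  A fully adiabatic, unperfused configuration is rejected as
singular with a pointer to the missing anchor.

## Cerebrospinal fluid

The reference experiment solved buoyant CSF flow; this package does not.
CSF is a conducting solid with an optional effective-conductivity
multiplier (`calibration.csf_conductivity_factor`, default 1.0 = pure
conduction) standing in for convective mixing.  This is the model's main
physical approximation and the documented reason its cooling curve runs
warm (below).

## Calibration

The only calibrated quantity is the pre-cooling baseline.  The rewarming
curve of the reference experiment approaches ~36.4 degC, and because
deep-tissue temperature is perfusion-pinned at `Ta + ~0.25` degC — no
skin-convection constant can move it — the arterial temperature defaults
to `Ta = 36.15` degC, which places the stationary cord center at
36.44 degC.  Physiologically this reads as mild systemic hypothermia of
the anaesthetised subject in a 30 degC theatre; there is no closed-loop
thermoregulation in the model.  The skin constant C (default 2.0) shapes
only the subcutaneous boundary layer and is exposed for sensitivity
studies, as is `Ta`.

## Protocol and outputs

The default protocol mirrors the reference experiment: stationary
equilibration, 30 min of cooling (set-points 20/16/12/8 degC; 20 is the
default), then 30 min with the lumen adiabatic, the cooling terminal
field seeding the stoppage phase unchanged.  Probes (default: the
cord-region centroid) are sampled every 10 s; series go to CSV, field
snapshots to ASCII VTK, maps to PNG with a fixed colour range.  Every run
writes a provenance file (resolved config, package version, registry
hash) that can be re-run bit-identically — the pipeline contains no
randomness.

Working resolutions: "desk" fidelity (1 mm, dt 0.5 s, ~71k tissue cells)
runs a full protocol in about a minute and is used for the routine
checks; "paper" fidelity (0.5 mm, dt 0.02 s) reproduces the reference
time step and is a configuration switch, not the test default.  The test
suite scales its refinement studies accordingly (transient dt-refinement
on a reduced 130 x 120 mm torso, grid refinement via the steady cooled
state), a deliberate problem-size choice documented here rather than in
the tests.

## Agreement with the reference experiment, and its limits

At desk scale with the defaults, against the printed cord-center series
at a 20 degC set-point:

* rewarming (+2/+4/+6/+8/+10 min): within 0.08-0.24 degC of the printed
  values, monotone, qualitatively and quantitatively reproduced;
* cooling: the 2 min point agrees within 0.37 degC, the curve is
  monotone with the printed near-plateau shape, but from 5 min onward
  the model runs systematically +0.64..+0.76 degC warm (e.g. plateau
  34.12 vs 33.36 degC), and the rewarmed cord is still 0.41 degC below
  baseline at +10 min where the experiment reports ~0.13.

Grid refinement accounts for only ~0.1-0.2 degC of that bias; the
remainder is physics held fixed by design: conduction-only CSF cannot
carry the dorsal cold around the cord the way the reference's CSF flow
analysis does (raising the CSF multiplier to ~2-3 closes the gap, but the
default deliberately stays at 1.0 so the approximation is visible rather
than calibrated away), and the anatomy dimensions are unpublished.  The
effective rewarming time constant of the model (~350 s) matches the
cord's perfusion constant, while the reference rewarms faster (~190 s) —
consistent with the same missing convective transport.

What the verification shows: the discretization solves the stated PDE
correctly (oracle and manufactured-solution convergence), conserves
energy globally to 1e-11, preserves the discrete maximum principle, and
responds monotonically to the coolant set-point.  What it cannot show:
that the defaults reproduce an experiment whose geometry and blood model
were never published — the cooling-phase bias above is the honest measure
of that gap.

## Known limitations

* Two-dimensional: no axial conduction or axial CSF/blood transport.
* No CSF hydrodynamics (surrogate multiplier only); stored CSF viscosity
  is unused unless that surrogate is enabled.
* Constant tissue properties; no temperature dependence, no
  thermoregulatory feedback on `Ta` or perfusion.
* Single annular catheter wall; the dual counter-current channels are
  collapsed into one isothermal coolant at the set-point.
* Uniform volumetric perfusion in bone taken at face value, as are the
  unusually large dura and viscera perfusion rates of the source tables.
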