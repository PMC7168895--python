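# Methods

This note documents the models, numerics and design choices behind
`hemoflow`, and what the synthetic study does and does not demonstrate.

## Blood rheology

Whole blood is modelled as a Casson fluid:

    sqrt(tau) = sqrt(tau_y) + sqrt(k * gamma_dot)   for tau > tau_y
    gamma_dot = 0                                   for tau <= tau_y

with yield stress `tau_y` [Pa] and Casson constant `k` [Pa·s]. `k` is
taken in Pa·s so that the apparent viscosity
μ(γ̇) = (√(τ_y/γ̇) + √k)² tends to `k` at high shear, matching the
measured high-shear plateau of whole-blood viscosity curves (≈ 3–5 cP).
μ diverges as γ̇ → 0; evaluation clamps the shear rate at
`gamma_min = 1 s⁻¹`, the lowest shear rate a scanning capillary-tube
viscometer calibrates, which bounds the solver's viscosity at
(√τ_y + √k)² and avoids committing to any extrapolation below the
instrument range. Internal units are SI; curves and reports use cP
(1 cP = 10⁻³ Pa·s).

**Fitting.** With τ_i = μ_i·γ̇_i, the law is exactly linear in
(√γ̇, √τ); ordinary least squares there recovers (√τ_y, √k) with no
initialization. A negative intercept is clamped to τ_y = 0 and the slope
refit through the origin (physical non-negativity). The noise model for
synthetic curves is multiplicative Gaussian on viscosity (relative SD
`noise_sd`, default 2%). At that noise the mean relative error over
repeated fits is below 5% for both parameters, but the *yield stress*
carries an absolute noise floor of roughly 0.5 mPa — the intercept
scatters in √Pa space — so recovery of τ_y near the bottom of the
physiological range (2 mPa) is relatively worse than k.

**Casson–Poiseuille oracle.** The closed-form tube flow rate
Q = (πGR⁴/8k)(1 − (16/7)ξ^{1/2} + (4/3)ξ − (1/21)ξ⁴), ξ = τ_y/τ_w,
with Q = 0 once the plug fills the tube, is implemented as an
independent analytic target for validation.

## Geometry

Domes are spherical caps: sphere radius R cut by the neck plane at
signed offset c (|c| < R; c < 0 means the dome bulges past its equator).
Morphometrics on triangulated caps follow the clinical definitions:
height = maximum signed distance to the neck plane along its normal
(the height axis is the neck normal, which makes "width orthogonal to
height" unambiguous); width = maximum pairwise distance of dome
vertices projected into the neck plane (dome side only); ostium
diameter = maximum pairwise distance of boundary-loop vertices; ostium
area by the shoelace formula on the angularly-ordered boundary polygon
(valid for star-shaped necks, which all generated geometries are).
Automatic neck detection on arbitrary clinical meshes is intentionally
out of scope: the neck plane is an input. Size classification uses the
5 mm height cutoff with `height <= 5` counted as small.

## 2D simulation domain

The solver operates on the aneurysm mid-plane: a straight channel of
width equal to the parent-artery diameter (default 4 mm) and length 10
diameters, with a circular-segment dome opening through a neck gap in
the upper wall. The domain is a uniform marker-and-cell grid with cells
masked fluid/solid; the curved dome wall is staircase-approximated. The
grid spacing snaps so the channel width is an integer cell count (the
inlet length is then exact). All solver-derived quantities are 2D
analogs: "dome volume" is the dome area, "dome surface" the dome wall
arc. Reported speeds are kept physiological by prescribing the area-mean
inlet speed as Q/A with A = (π/4)·d² — the 2D channel carries the same
mean speed a circular artery of that calibre would at the prescribed
flow rate.

## Flow solver

Incompressible generalized-Newtonian Navier–Stokes with μ from the
Casson law at the local scalar shear rate γ̇ = √(2D:D). Discretization:

- staggered (MAC) velocity/pressure layout; first-order upwind
  advection and variable-viscosity diffusion assembled implicitly per
  momentum component; the transpose part of the stress divergence
  ∇·(μ∇uᵀ) is lagged (it vanishes identically for constant μ).
- no-slip walls via ghost values. The tangential ghost uses the
  quadratic through the wall zero, the face centre and the opposite
  neighbour (u_ghost = −2u_C + u_opp/3), which keeps the 5-point stencil
  and makes the wall gradient second-order; a linear reflection is the
  fallback where no opposite leg exists. This matters: with the linear
  reflection the wall shear stress error at the default spacing is
  2–3%; with the quadratic ghost it is below 1%.
- incremental pressure projection: a constant-coefficient Poisson solve
  (factorized once per domain) restores a discretely divergence-free
  field at every nonlinear iteration; mass is conserved to machine
  precision, which also makes the stream function path-independent.
- outlet: zero streamwise gradient with the outlet flux scaled to the
  instantaneous inlet flux — a desk-scale stand-in for a traction-free
  boundary; pressure is defined up to the pinned constant.
- nonlinearity: Picard iteration on μ(γ̇) and the advecting velocity,
  stopped at a relative velocity increment below 0.01 or 50 iterations
  (typically 1–3 per step at the default time step). Hitting the cap
  raises a warning and flags the solution, it does not abort.
- time stepping: implicit per step (the Casson viscosity at low shear
  makes explicit diffusion hopeless); default Δt = T/200. Steady
  solutions are obtained by pseudo-time marching the same scheme to a
  fixed point (Δt = 0.05 s, relative change < 10⁻⁵).

**Boundary protocol.** Pulsatile inflow Q(t) = Q̄(1 + A sin 2πt/T) with
Q̄ = 2.6 mL/s (published mean cerebral-artery flow rate), A = 0.5 and
T = 1 s (60 bpm; the waveform shape beyond its mean is a modelling
choice — a single harmonic gives well-defined peak-systole (T/4) and
end-diastole (3T/4) instants and is configurable). Density
ρ = 1060 kg/m³ (standard whole blood). The inlet profile is parabolic
(fully developed); the run covers 4 cardiac cycles and reports the
second. Because each run starts from the steady solution at Q(0),
start-up transients are already negligible in cycle 2 (cycles 3 and 4
agree to ~10⁻⁹ in the tests); the 4-cycle protocol is kept as the
configured default for fidelity to clinical practice.

**Validation.** The solver contract is the analytic-oracle suite, not a
particular scheme: plane Poiseuille (L2 velocity error 0.008% at the
default 0.2 mm spacing), the two-zone plane-Casson wall stress (0.78%),
quasi-steady pulsatile agreement with instantaneous steady solves
(< 2% at T = 50 s), Stokes-regime linearity under flow doubling, mass
conservation, and < 5% change in dome-averaged shear rate under one
uniform refinement from the default spacing.

## Hemodynamic metrics

Scalar shear rate √(2D:D) (zero for rigid rotation, the shear
coefficient for simple shear). Dome averages are arithmetic means over
dome cells (equal measures on the uniform grid). Wall WSS is
μ(γ̇_w)·γ̇_w with γ̇_w the one-sided quadratic estimate of the tangential
velocity gradient at each solid wall face (exact for a parabolic
profile). TAWSS is the per-sample trapezoidal (1/T)∫|WSS_i|dt over the
stored report cycle, then area-averaged over the dome wall into the
per-patient scalar. "Minimal/maximal WSS" defaults to the global
extremum over dome samples × cycle times, per the definition "lowest and
highest value during one cardiac cycle over the dome surface"; the
alternative reading (area-average of per-sample temporal extrema) is
available as `extrema_mode="spatial_mean"`.

## Flow patterns

Evaluated at peak systole. The stream function is integrated from the
face fluxes (exact for the projected fields). A recirculation zone is an
interior ψ-extremum scored by its closed-level-set depth: the drop from
the extremum to the level where its surrounding level set first touches
the dome boundary (wall or ostium line) or merges into a stronger zone —
beyond that level the streamlines are no longer closed inside the dome.
Extrema with depth ≥ 1% of the dome ψ-range count; the threshold
suppresses numerical micro-eddies, never increases the count when
raised, and replaces the visual zone counting of clinical practice with
a reproducible rule. Zero or one zone is "simple", two or more
"complex" (the zero-zone case does not arise in the clinical definition
and is mapped to simple). The inflow jet is classified by seeding
streamlines at the top-decile-speed ostium faces and tracing them (RK4)
to their first close approach to the dome wall: "concentrated" if the
median impingement angle lies within ±30° of the tip direction (neck
normal through the apex), else "diffused". The decile and angle window
are package conventions for an otherwise qualitative criterion.

## Statistics

Groups are summarized as mean ± sample SD (n−1). Each variable is gated
by Shapiro–Wilk per group at α = 0.05: both normal → pooled-variance
Student t-test (Welch behind a flag); otherwise two-sided Mann–Whitney,
exact enumeration for tie-free groups of ≤ 20, normal approximation
with tie correction beyond. No multiple-testing correction is applied
(matching the clinical analysis). Reporting conventions: percent
increases truncate to one decimal (how 63.1% arises from means 3.8 and
6.2), fold changes round half-up; p-values print with a "<0.001" floor.
Under the null the gated procedure's type-I rate at n = 16/5 is ~5.6%
(2000 replicates).

## Synthetic cohort

16 small + 5 large patients. Per group, dome height and ostium diameter
are drawn from truncated normals (small height on (0.5, 5], large on
(5, ∞), ostia and parent diameters positive) whose *truncated* moments
are calibrated to the clinical group statistics — the published
mean ± SD describe the size-gated populations, so matching the
truncated moments, not the untruncated parameters, reproduces them in
large samples (small height 3.4 ± 0.8 mm recovered to 1%/3% at n = 6000).
The large-group height SD of 2.4 mm is unreachable for a lower-truncated
normal whose mean is only 1.2 mm above the bound (a truncated normal's
SD cannot exceed its mean excess); there the mean alone is matched at
the nominal sigma, giving 6.2 mm mean with a smaller spread. The
spherical cap is solved exactly from each (height, ostium) pair
(R = (H + O²/4H)/2, c = R − H); width then emerges from the cap family
(W = max(O, 2R)) and lands near the clinical group means (≈ 4.9 vs 4.5
mm small, ≈ 7.6 vs 7.4 mm large). Parent diameter ~ N(4.0, 0.4) mm
truncated positive (typical intracranial artery; inlet area = (π/4)d²).
Rheology: τ_y ~ U[2, 20] mPa, k ~ U[3, 5] mPa·s — a physiological band
resembling measured whole-blood curves, explicitly not fitted to any
published patient values (none are printed). Each patient receives a
noisy synthetic viscometer curve and the solver consumes the *refit*
parameters, exercising the fitting path end-to-end. Everything is a
pure function of the master seed.

## What the synthetic study shows — and does not

Patient-level geometries and rheology of the clinical cohort are
unpublished, so the study's absolute magnitudes are not reproducible by
construction; only the morphology distributions are calibration targets,
and the hemodynamic contrasts must *emerge* from the solver. At the
study conditions (default cohort, coarse fast preset: 0.25 mm grid,
Δt = T/100, 2 cycles reporting the second, fixed seed) the clinical
directions reproduce: large-group dome shear rate below the small group
(significant), dome viscosity above (significant), TAWSS below. The
magnitudes are 2D analogs: dome shear rates of tens of s⁻¹ rather than
hundreds, TAWSS of ~0.15 Pa rather than a few Pa — expected from the
mid-plane geometry, the first-order upwind advection (which smears the
inflow jet at Re ≈ 200), and the staircase dome wall.

Known limitations:

- the viscosity direction depends on the cohort draw at n = 5 large
  patients: inter-patient rheology variation (τ_y spanning a factor 10,
  drawn independently of size group) can exceed the compressed 2D size
  effect on dome shear rate, so at some seeds the group viscosity
  contrast inverts. This mirrors a real design vulnerability of small
  two-group studies rather than a code defect.
- no vessel curvature or bifurcations; the parent vessel is straight
  and the neck is mid-vessel.
- rigid walls, laminar flow, single-harmonic waveform, parabolic inlet
  — all standard assumptions of the clinical pipeline being emulated,
  kept configurable where the underlying choice was unstated.
- the recirculation count and jet labels are deterministic surrogates
  for visual classification; their thresholds (1% circulation depth,
  ±30° window, top decile) are conventions, validated on planted-vortex
  and synthetic-jet fields.
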