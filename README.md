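# hemoflow

Desk-scale, patient-specific hemodynamics of unruptured cerebral
aneurysms with measured-style non-Newtonian blood rheology.

Clinical CFD studies of saccular ("berry") aneurysms compare small
(height ≤ 5 mm) and large (> 5 mm) lesions by simulating pulsatile blood
flow in each patient's reconstructed lumen and reducing the fields to a
handful of dome metrics: average shear rate γ̇ and apparent viscosity μ at
peak systole (PS) and end diastole (ED), and the minimal, time-averaged
and maximal wall shear stress (WSS) on the dome. Large aneurysms show
lower dome shear rate and WSS and higher blood viscosity — the signature
of stagnating, shear-thinning blood in a larger sac. `hemoflow`
re-implements that entire analysis chain as a tested Python library with
a synthetic virtual cohort in place of patient data, at a 2D "mid-plane"
scale that runs on a laptop.

## What is inside

- **Rheology** — the Casson yield-stress law
  √τ = √τ_y + √(k·γ̇), i.e. μ(γ̇) = (√(τ_y/γ̇) + √k)², fitted to
  viscometer curves (1–1000 s⁻¹, viscosity in cP) by exact linear
  regression in (√γ̇, √τ); plus the closed-form Casson–Poiseuille pipe
  flow used as a solver oracle.
- **Geometry** — spherical-cap dome meshes (STL I/O), the five standard
  morphometrics (height H, width W, ostium diameter O, ostium area,
  surface area) and the 5 mm small/large classification.
- **Flow solver** — unsteady incompressible generalized-Newtonian
  Navier–Stokes (∇·u = 0, ρ(∂u/∂t + u·∇u) = −∇p + ∇·(2μ(γ̇)D)) on a
  masked staggered grid: channel (parent artery) plus circular-segment
  dome, parabolic pulsatile inlet with cycle mean 2.6 mL/s, rigid no-slip
  walls, outflow outlet; implicit upwind advection–diffusion with Picard
  iteration on μ(γ̇) (relative tolerance 0.01, ≤ 50 iterations), four
  cardiac cycles with the second reported.
- **Hemodynamics** — γ̇ = √(2D:D), dome averages, wall WSS sampling,
  TAWSS = (1/T)∫|WSS_i|dt, dome extrema.
- **Flow patterns** — stream-function recirculation counting
  (simple = ≤ 1 zone, complex = ≥ 2) and inflow-jet classification
  (concentrated vs diffused) from streamline impingement.
- **Statistics** — mean ± SD group summaries, Shapiro–Wilk-gated
  Student t / exact Mann–Whitney comparisons at α = 0.05, and the
  reporting arithmetic (truncated percent increases, half-up fold
  changes).
- **Synthetic cohort** — 16 small + 5 large virtual patients with
  group morphology calibrated to the clinical means/SDs and per-patient
  Casson rheology fitted from noisy synthetic viscometer curves.

## Worked example

```sh
python examples/04_single_patient.py
```

```
dome: height 3.4 mm, ostium 4.5 mm
avg shear rate   PS    45.9 1/s   ED    16.3 1/s
avg viscosity    PS    6.92 cP    ED    9.75 cP
dome-wall WSS    min 0.0003  time-avg 0.1501  max 1.5299 Pa
flow pattern     1 recirculation zone(s) -> simple; inflow jet diffused
```

A small aneurysm at the group-mean morphology: the dome shear rate
(~46 s⁻¹ at peak systole) is far below the parent-vessel scale, so the
shear-thinning blood is locally more viscous (6.9 cP vs the ~4 cP
high-shear plateau); the wall WSS peaks near the neck and nearly
vanishes at the dome tip. One recirculation zone with a wall-following
inflow is the "simple/diffused" pattern typical of small unruptured
aneurysms. The other examples cover rheology fitting, morphometrics,
solver validation against closed forms, and a reduced cohort study.

A thin CLI mirrors the library:
`hemoflow fit-viscosity`, `morph`, `simulate`, `cohort`, `run-study`,
`report` (see `hemoflow --help`).

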