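# Methods

## The exposure model

The package computes the electromagnetic field inside isolated
mitochondria at the bottom of a cylindrical glass incubation chamber
filled with saline and illuminated from above by a continuous-wave
near-infrared laser with a flat-top beam profile.  Because the beam is
laterally uniform over the ~1 cm² chamber cross-section and normally
incident, the empty chamber reduces to a 1D planar multilayer — air,
saline (t_ss = 5 mm), glass (t_g = 2 mm), air — solved exactly for a
monochromatic plane wave.  All phasors use the e^{+jωt} convention with
n = n′ − jn″ (n″ ≥ 0), so forward waves decay and outgoing spherical
waves carry e^{-jkr}; the absorption coefficient relates to the
imaginary index through μₐ = 4πn″/λ₀.

The source amplitude follows from the stated power density in air,
E₀ = √(2η₀S); 1 W/cm² gives 2744.9 V/m.  Optical constants for saline
(treated as pure water — the solute molarities are too low to shift the
NIR index) and borosilicate glass are tabulated at 808, 980 and
1064 nm; no interpolation is offered because dispersion across each
narrow laser line is negligible and no constants exist between the
lines.  Mitochondria are homogeneous prolate spheroids — l_m = 3 µm
long, d_m ∈ [0.4, 1.2] µm (study grid {0.5, 0.75, 1} µm) across, with
effective n′_m ∈ [1.35, 1.45] and μ_a,m ∈ [20, 150] m⁻¹, the same
ranges at all three wavelengths.

### 1D transfer-matrix stage

`multilayer` solves the stack by backward substitution: the transmitted
wave is normalized, tangential E and H are propagated up through every
interface, and the solution is rescaled to the source amplitude.
Field evaluation propagates total fields from the *nearest* interface
with transmission-line relations rather than from per-layer amplitude
phases; across millimetric layers the phase argument reaches ~4 × 10⁴
rad, and the nearest-interface form keeps interface continuity exact to
machine precision instead of ~10⁻⁸.  Layer-averaged doses use the
closed-form integrals of the piecewise-exponential intensity (a
Gauss–Legendre path is retained as a cross-check for thin layers; it is
*not* adequate for the 5 mm saline column, whose ~13 500 standing-wave
fringes defeat any practical global quadrature).

A 5-layer variant inserts an effective homogeneous "mitochondria
layer" (t_m ~ 1 or 3 µm) resting on the glass: the rough 1D model of
the experiment, and the reference for the 3D-versus-1D comparisons.

### Scenes

`scenes` builds the study configurations.  All bodies rest on (or stack
up from) the floor at z = 5 mm:

* **isolated** — one horizontal body, long axis along x;
* **seven_horizontal** — a central body, two coaxial end-to-end
  neighbors and four side-by-side neighbors, one layer, uniform surface
  gap g (default 0.05 µm);
* **seven_vertical** — seven standing bodies, hexagonal in plan with
  center-to-center pitch d_m + g, occupying the last 3 µm of saline;
* **three_layer_21 / …_rot90** — three vertically touching copies of
  the 7-pattern (occupied height 3·d_m, matching the standing-body
  height at d_m = 1 µm); the middle layer optionally rotated 90°;
* **periodic_array** — a finite odd×odd tiling (default 9×9, pitch
  l_m + g by d_m + g) standing in for a periodic arrangement; the dose
  is read from the central cell, and growing 5×5 → 9×9 moves it by
  < 1% (checked in the tests);
* **random_scene** — seeded, non-overlapping horizontal bodies with
  uniform in-plane positions/azimuths, for robustness tests.

The in-plane gap g is a modeling parameter: real preparations do not
have a defined spacing, and published figures of such arrangements are
not dimensioned.  The default g = 0.05 µm represents densely settled
organelles.  Dose results for laterally adjacent bodies are weakly
sensitive to g, but the *vertically extended* configurations are not
(see "Known systematics" below).  Scenes serialize to YAML;
overlap checking reduces to exact plan-view ellipse tests for bodies
sharing a mid-plane (conservative circumscribed polygons), with
bounding-sphere and z-slab prechecks.

Voxelization marks every lattice point strictly inside a body, tags it
with its owner, and is validated against analytic volumes (< 2% error
at the default spacing).

### Coupled-dipole solver

`solver` computes internal fields with a volume discrete-dipole method
in a homogeneous saline background, driven by the exact layered-chamber
incident field (the no-mitochondria 4-layer solution evaluated at the
voxel depths).  Reflections of the *scattered* field at the
saline–glass interface are neglected: the interface Fresnel coefficient
is ≈ 0.06 and the scatterers are weak, so the neglected correction is
second-order small.  Each voxel of spacing d carries the SI
Clausius–Mossotti polarizability with radiative-reaction correction

    α_CM = 3 d³ (ε_rel − 1)/(ε_rel + 2),   ε_rel = ε_m/ε_b,
    α = α_CM / (1 + j k³ α_CM / 6π),

and the self-consistent system p_i = ε₀ε_b α_i (E_inc,i + Σ G_ik p_k)
is solved by GMRES (fixed Born initial guess, fixed ordering, relative
residual 10⁻⁶ — fully deterministic).  The translation invariance of
the dyadic Green function on the lattice turns each matrix–vector
product into six FFTs on a zero-padded grid.  The macroscopic internal
field follows from the polarization-density relation
p = ε₀(ε_m − ε_b)d³ E_int; H inside the bodies is the incident H plus
the dipole-radiated magnetic field (one extra convolution), which is
smoother than a discrete curl.

**Validation.**  The engine is checked against an independently written
Mie series for a sphere in saline: absorbed, extinguished and scattered
power agree to 0.3–0.9% for diameters 1–3 µm up to the maximum contrast
(n′ = 1.45, μₐ = 150 m⁻¹), and the optical theorem
(extinction = absorption + far-field-integrated scattering) holds to
10⁻⁵.  Doses change by < 1% when the default spacing λ₀/(20 n′_m) is
halved.

The Born mode sets E_int = E_inc (with an optional static
depolarization correction per ellipsoid axis, off by default: the
quasistatic shape factors overcorrect wavelength-sized bodies).  The
difference between Born and the full solution vanishes linearly with
the permittivity contrast, as it must for a neglected first-order term.

### Dosimetry

Volume averages reduce to means over a body's voxels (this cancels the
voxelized-volume error).  With peak-amplitude phasors,

    Ed = ⟨ (ε₀ ε′_m |E|² + μ₀ |H|²)/4 ⟩,
    Pd = ⟨ ω ε₀ ε″_m |E|²/2 ⟩.

Range statistics summarize a dose over a sweep by the midpoint of
[min, max] and the "range radius" (half the spread) — the convention
that reproduces all printed (mean, radius) pairs of the study's
discussion — and the total absorbed power extrapolates a mean Pd to the
full 10⁻¹⁰ m³ of organelles implied by 50 µg of mitochondrial protein
at 0.5 g/ml.

## Problem sizes and defaults

| quantity | default | rationale |
|---|---|---|
| source power density | 1 W/cm² | stated experimental irradiance |
| voxel spacing (quoted results) | λ₀/(20 n′_m) ≈ 35 nm | ~20 samples per in-medium wavelength; halving changes doses < 1% |
| voxel spacing (sweeps) | λ₀/(10 n′_m); λ₀/(7 n′_m) for 21-body and periodic | keeps the 90-run sweep at ~1–2 min per wavelength; guarded by the convergence test |
| GMRES tolerance | 10⁻⁶ relative | far below the few-percent physical tolerances |
| periodic tiling in sweeps | 5×5 | central-cell dose within 1% of 9×9 |
| surface gap g | 0.05 µm | densely settled organelles; undimensioned in reality |

## What the generator does and does not emulate

The scene builders reproduce idealized arrangements — monodisperse,
rigid, homogeneous spheroids at fixed gaps.  Real preparations have
polydisperse, deformable organelles with internal membrane structure,
partially stacked and at random spacings; the random-scene generator
varies positions and azimuths but not sizes or shapes.  Passing tests
therefore demonstrate correctness of the electromagnetic solution for
the stated geometry class, not biological fidelity of any single
arrangement; the parameter sweep (diameter × index × polarization ×
configuration) is the intended way to bracket that uncertainty.

## Known systematics: open-domain focusing in tall configurations

For configurations that extend ~3 µm along the propagation direction —
standing (vertical) bodies and the three-layer stack — the open-domain
solution develops a genuine traveling-wave focusing buildup: the
forward-scattered field stays nearly phase-matched with the incident
wave over the body length (beat length λ₀/(n_eff − n_ss) ≫ 3 µm), so
|E| grows toward the exit end, the way a dielectric rod antenna
concentrates a co-propagating wave.  For a single standing d_m = 0.5 µm
body at n′_m = 1.45 the volume-averaged |E|² gains ~40–60%; a dense
hexagonal bundle of seven shows a similar collective effect, strongly
dependent on the packing gap (g = 0.05 µm → +40%; g = 0.25 µm →
essentially none).  The three-layer stack raises its middle/bottom
central doses by ~6–10% through the same mechanism.  We verified the
effect is not a discretization or truncation artifact: it is
grid-converged, the engine matches Mie theory at matched size and
contrast, and an independent 2D finite-difference frequency-domain
solver reproduces it with either a PML or an incident-driven impedance
boundary placed 1.5–2.5 λ₀ away.

Published mesh-based results for nominally similar tall arrangements
report much weaker inter-layer and alignment effects; with the packing
gap undimensioned there, the most likely reconciliation is sparser
packing.  Consequently the package's sweep statistics for tall, densely
packed configurations sit above mesh-based literature values, while
isolated and single-layer results agree to ~2%.  Quantities dominated
by the tall configurations (polarization spread of the 21-body model,
diameter sensitivity, sweep range midpoints) inherit this systematic;
single-body and single-layer doses do not.

## Limitations

* Oblique incidence, Gaussian beams and partial coherence are out of
  scope (the flat-top source justifies the plane-wave model).
* The layered-background Green function is not implemented; scattered
  fields do not re-reflect at the saline–glass interface.
* No thermal (temperature-rise) modeling, no exposure-duration
  accounting, and no claims about downstream biology.
* Exterior scattered-field evaluation below the floor treats the glass
  as saline (used only for diagnostics, never for doses).
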