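# Methods

`enmkit` is a hybrid electro-neuro model (ENM) of electrical stimulation of a
large human peripheral nerve (the sciatic nerve) through intraneural (TIME)
and extraneural cuff (FINE) electrodes.  It couples a quasi-static volume
conductor, which yields the extracellular potential produced by a unit
current at each electrode active site (AS), to a compartmental model of
myelinated sensory axons, which decides whether a given stimulus recruits a
given fiber.  Fascicle-level recruitment statistics then grade electrode
designs and stimulation policies by their ability to recruit individual
fascicles selectively.

## Nerve geometry

A cross-section is a 2D description in mm: an outline polygon, and one
polygon per fascicle.  Each fascicle carries a perineurium sheath of
thickness 3% of its equivalent diameter (the diameter of the equal-area
circle); the interior is endoneurium, the space between fascicles is
epineurium, and the nerve is immersed in saline.  The section is extruded
along z (default 30.8 mm, the solver's ±15.4 mm domain).

Two built-in synthetic anatomies emulate published sciatic sections:

* **proximal** — 37 fascicles in an 18.7 × 8.8 mm ellipse (the source
  literature prints "187 × 88 mm", a unit slip), with a total fascicular
  area of 56.25 mm² implied by the reported whole-nerve fiber count
  (13.5 k fibers at 240 /mm²);
* **distal** — 31 fascicles in an 11.5 × 6.4 mm (≈58.2 mm²) ellipse, with
  the same areal fill fraction (≈0.435) as the proximal section.

The generator draws equivalent diameters from a truncated log-normal
(σ = 0.5, median tuned to the area target, support [0.15, 2.0] mm), enforces
at least two fascicles in each size class (small < 0.4 mm < medium < 0.8 mm
< big), rescales the big class onto the area target, and packs gently
perturbed circles (wave amplitude ≤ 4% + 2%) largest-first by rejection
sampling with a 50 µm minimum clearance and a 0.15 mm boundary margin.
Everything is driven by a seeded generator: the same seed reproduces the
geometry bitwise.  Real, segmented cross-sections can be supplied instead
as a plain-text contour file (`NERVE` / `FASCICLE <id>` blocks of `x y`
vertices in mm); the envelope shape is then arbitrary.

What the generator does *not* emulate: fascicle shapes other than wavy
circles, spatial correlation of fascicle sizes (real sciatic sections group
large fascicles), paraneurium, and any deformation of the nerve by the
implant.  Score-type results therefore transfer to real anatomies only at
the level of trends (AS-count saturation, implant-count gains, policy
ordering), not as patient-specific percentages.

## Electrodes

**TIME** (transversal intrafascicular multichannel electrode): a 20-µm
polyimide ribbon inserted across the nerve along the major axis; width
0.380–0.670 mm (linear in AS count over {12, 16, 20, 24}); shaft length
18 mm (proximal) / 10 mm (distal); circular ⌀60 µm ASs, half per face,
evenly pitched with the two faces offset by half a pitch.  The pitch is
`L/(n/2 + 1)`, i.e. a full-pitch end margin; this keeps every site inside
the elliptical outline when shafts are implanted parallel at off-center
heights.  Parallel multi-implant placements put 1–4 shafts at fixed
fractions of the minor axis ({0.5}, {0.27, 0.73}, {0.27, 0.5, 0.73},
{0.27, 0.42, 0.58, 0.73}), chosen to cover the nerve height while sharing
shaft positions between implant counts.

**FINE** (flat interface nerve electrode, no-compression variant): a
rectangular frame of inner opening 18.75 × 8.85 mm (proximal) or
10.9 × 7 mm (distal) with 0.5 × 0.5 mm square ASs split evenly between the
two long inner faces; 12–24 ASs (the distal frame fits at most 20).  The
stated distal opening is narrower than the distal nerve's major axis; since
no compression is modelled, the opening auto-expands to the nerve bounding
box when needed.  The frame walls are 0.3 mm insulating substrate and the
cuff extends 5 mm axially.

## Volume conductor

The extracellular potential solves ∇·(σ∇V) = 0 with a unit current on one
AS and V = 0 on the boundary of a saline cylinder (diameter
max(16 mm, nerve bounding box + 4 mm), length ±15.4 mm).  Conductivities
(S/m): saline 2, epineurium 0.0826, endoneurium (0.0826, 0.0826, 0.571)
with the large value along the nerve, perineurium 0.00088, polyimide
6.67·10⁻¹⁴.

Discretization is a cell-centered finite-volume scheme on a nonuniform
tensor-product grid, with two-point fluxes and harmonic averaging.
Numerical choices that matter:

* fine windows follow the electrode (default 0.15 mm in-plane near the
  shaft, 0.12 mm across the ribbon plane and the AS plane, 0.25 mm axial),
  grading outward with the neighbour-size ratio capped at 1.35;
* the perineurium (9–60 µm) is far below the grid scale and enters as a
  thin-film series resistance t/σ_p on faces crossing a fascicle boundary;
* the TIME ribbon (20 µm) is a set of zero-conductance faces on its plane;
  its AS is a current source in the cell touching the correct face, so the
  insulating shadow of the shaft is exact at grid resolution.  FINE walls
  are excluded substrate cells, with the AS current spread over the wall
  face cells covered by the 0.5 mm pad;
* cells outside the cylinder are grounded, and grounded ghost faces back
  the six outer box walls (on coarse grids the stair-step cylinder alone
  would leave most of the boundary insulating);
* when all placements are centered at z = 0 (always, in the shipped
  experiments) the domain is mirror-symmetric and only z ≥ 0 is solved,
  with the source current halved and the solution mirrored.

Verification imposes closed-form point-source solutions as Dirichlet data
and reproduces them within 10% at 0.5–4 mm probes (isotropic and
anisotropic).  Residual near-field error at the default/coarse profiles is
a known bias: at 0.3 mm from a site the coarse profile overestimates |V| by
roughly 20%, converging by 1 mm; fascicle-level thresholds inherit a small
downward bias from the fibers closest to the site.

One linear system serves all ASs of an electrode (only the right-hand side
changes); systems up to ~10⁵ unknowns are factorized (sparse LU, minimum
degree ordering), larger ones use ILU-preconditioned GMRES with a verified
true residual below 10⁻⁵.  Potentials are stored per ampere on the grid and
interpolated trilinearly; bipolar modes are signed superpositions of lead
fields, which is exact by linearity.

## Fibers and biophysics

Each fascicle is filled with Aβ-range myelinated fibers at a configurable
endoneurial density (240 /mm² at full scale — itself a 50× reduction of the
anatomical density that the source model validated as recruitment-neutral).
Counts are Poisson(density × area) with a minimum of one fiber; positions
are uniform; fibers cluster into 1/3/5 populations (by fascicle size class)
as Voronoi cells of random interior centers.  Diameters are drawn from a
two-Gaussian mixture (modes 7 ± 1.3 and 12 ± 2.0 µm, equal weight,
truncated to [5.7, 16.0] µm) — a stand-in for the cited but unpublished
histological distribution, fully configurable — and snapped to the nine
tabulated MRG diameters.

The axon model is the McIntyre–Richardson–Grill double cable: 21 nodes of
Ranvier and 20 internodes of [MYSA, FLUT, 6×STIN] sections; nodal fast Na⁺,
persistent Na⁺, slow K⁺ and leak channels with 36 °C kinetics; passive
internodal axolemma under a myelin sheath (0.1 µF/cm² and 0.001 S/cm² per
membrane, 2·N lamellae membranes) with a periaxonal space (2–4 nm) coupling
compartments axially.  Geometry and channel densities follow the original
MRG tables at the nine diameters (no interpolation between rows); the
internode spacing uses the population rule L = 100·D rather than the MRG
table's native spacings, matching the nerve model this package reproduces.
Node ladders are shifted along z by a per-fiber uniform offset in [0, L).

Extracellular drive: the lead field is sampled at all 221 compartments
(nodes-only profiles are accepted and interpolated), scaled by the pulse
current, and applied as a rectangular cathodic pulse (default 50 µs).
Integration is backward Euler on the (V_axon, V_periaxonal) block-tridiagonal
system, 1 µs steps during the pulse and 5 µs after, 2 ms window, with
exponential gating updates lagged one step.  A fiber is recruited when the
membrane potential crosses 0 mV at *both* terminal nodes after stimulus
onset (the action potential traversed the whole fiber); integration stops
early once that is decided.  Ladder ends of the largest fibers (a 16 µm
fiber spans 32 mm) poke past the ±15.4 mm domain and clamp to the last
axial plane, where the grounded-boundary potential is negligible.

Thresholds are reported on the 60-point charge grid (0.5–60 nC at 50 µs,
i.e. 10 µA–1.2 mA).  The search runs one simulation at the cap and bisects,
which is exact under monotone recruitment; because fibers nearly touching a
site can show cathodal conduction block at extreme charges (a real
double-cable behavior), fibers silent at the cap whose peak drive exceeds
80 mV are re-probed at lower rungs, so the reported value is the first
recruiting charge of the bottom-up scan.

## Selectivity analysis

For a configuration c and charge Q, each fascicle i has recruited count
n_i and fraction µ_i.  Spatial selectivity Sel_i = µ_i − mean of the other
µ_j; functional selectivity Sel_s_i = n_i / Σ n_j.  Fascicle i is
*selectively recruited* by c if at any sweep charge Sel_i > 0.6 and
Sel_s_i > 0.9 (strict) with n_i ≥ 1.  An electrode's score is the
percentage of fascicles selectively recruited by at least one of its
configurations; the monopolar policy uses single cathodic sites, the
bipolar policy adds, per anchor site, its nearest opposite-face and
same-face partners in two equal-current patterns — opposed (−/+) and
matched anodic (+/+), the latter following the published "same
polarization" illustration.  The fascicle-level "perceptual" threshold is
the smallest sweep charge recruiting 10% of a fascicle's fibers; the
validation statistic averages it over ASs (nearest fascicle per AS) and
population seeds.

Simulations are pruned by the effective stimulation range (TIME 2 mm; FINE
4 mm proximal / 3 mm distal): fibers of fascicles with no fiber inside the
range around the driving site are skipped; an implicated fascicle keeps all
its fibers.  On a toy nerve the filtered and unfiltered selective sets are
verified identical.  Multi-implant evaluation unions the per-implant
selective sets, one configuration active at a time; each implant's lead
fields are solved with only its own shaft present (a 20 µm sheet 1–2 mm
away is a negligible field obstacle).

## Problem sizes and reproduction profiles

The shipped profiles are `desk` (coarse grid — 0.22 mm in-plane fine
windows, 0.35 mm axial; reduced density; 1–3 seeds) and `paper` (fine grid,
240 /mm², 10 seeds).  `scripts/acceptance.py` runs the desk profile:
density 36 /mm² with 3 population seeds for the score and threshold
experiments, and 18 /mm² with one seed for the 15-variant monopolar-vs-
bipolar comparison.  Scores are reported as means over seeds; the published
values these reproduce carry ±1 SD dispersions that are wide relative to
the residual desk-scale biases (near-field discretization, reduced density
granularity).

## Known limitations

* No nerve compression under FINE, no paraneurium, no electrode-tissue
  encapsulation; purely quasi-static (no dispersion, no interface
  impedance).
* Single-pulse recruitment only; no frequency encoding or adaptation.
* The diameter mixture is a configurable surrogate, not the cited
  histological table.
* Near-field potentials at sub-0.5 mm distances carry grid-level bias at
  the desk profiles; absolute thresholds of the very nearest fibers are
  correspondingly soft, while fascicle-level statistics are dominated by
  the better-resolved 0.5–2 mm band.
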