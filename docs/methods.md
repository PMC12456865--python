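# Methods

This note documents the models implemented in `nirpdt`, their assumptions,
the parameters that matter, and the numerical choices made where the
design was genuinely open.

## Phantom model

A phantom is a 3-D grid of tissue labels (AIR=0, SKIN=1, FAT=2, DUCT=3,
TUMOR=4) at an isotropic pitch, default 0.33 mm; the canonical cohort
geometry is 500³ voxels, but every operation treats the grid size as a
free parameter and the tests run at 80–120³.  Axis 2 is the
slice-stacking/body axis; the treatment beam travels along +z and enters
at the z = 0 face.  I/O supports NIfTI (pitch from the header, label
legend from a JSON sidecar) and ordered PNG/TIFF slice stacks with a
mandatory `stack.json` sidecar; round-trips are bit-identical.
Resampling to a new pitch is nearest-neighbour (labels are categorical),
preserving the label set and the physical extent to within one voxel.

**Breast density** is the duct fraction of the fibroglandular interior,
n_duct/(n_duct+n_fat); skin, air and tumor voxels never enter the ratio.
Density is computed and frozen on the phantom record *before* tumor
embedding, so relabelling duct voxels as tumor cannot shift the recorded
class.  CT-derived densities understate mammographic density, so
classification multiplies the raw density by 2.5, caps at 100 %, and bins
half-open: [0,25) fatty, [25,50) scattered fibroglandular, [50,75)
heterogeneously dense, [75,100] extremely dense.  The cap and the edge
rules are this package's choices; sources describing the classes give
ranges without edge conventions.  Representative selection picks the
group member closest to the mean density, ties to the lowest id.

## Synthetic phantom generator

The generator emulates what a prone breast-CT label map provides, so the
whole chain is testable without external data:

* **Contour** — a pendant hemiellipsoid (default semi-axes 40×40×60 mm)
  with its base on the chest wall (far z face) and apex toward the beam.
* **Skin** — all interior voxels within a Euclidean distance transform of
  `skin_thickness_mm` (default 1.5 mm — the order of real breast skin and
  ≥4 voxels at 0.33 mm) of air.  The shell is closed by construction and
  exactly one voxel thick when the thickness equals the pitch.
* **Ducts** — a seeded Gaussian random field smoothed to a correlation
  length (default 4 mm) and thresholded *by exact count* inside the fat
  interior, so the measured density matches the target to within one
  voxel (the ±0.02 tolerance quoted in tests is loose).  Target densities
  are restricted to [0, 0.45], the realistic cohort range.
* **Host block** — an optional solid duct cube (≥9 mm) whose *top face*
  sits `host_depth_mm` below the apex skin along the beam axis.  It
  guarantees a feasible embedding site at that depth regardless of
  random-field luck and is flagged in the provenance record.  (Placing
  the block top at the requested depth, rather than centring the block
  there, is what makes "host at d mm → tumor depth d" hold.)
* **Cohorts** — raw densities drawn from a piecewise-uniform mixture
  matching the observed cohort histogram (56 % below 0.10, 30.7 % in
  0.10–0.20, 11.3 % in 0.20–0.30, 2 % in 0.30–0.45); records carry the
  generator's voxel-tally ground truth.

What the generator does *not* emulate: Cooper ligaments, vasculature,
chest-wall anatomy, realistic duct branching topology, or the
patient-to-patient contour variation of a real cohort.  Tests passing on
these phantoms therefore validate the pipeline's mechanics and scaling
laws, not anatomical fidelity.

## Tumor embedding

Early disease is modelled as DCIS: a 7-mm sphere confined to the ducts.
Sphere membership is voxel-centre inclusion, which matches the analytic
volume (π/6)d³ to within 2 % at 0.33 mm pitch.  Feasible centres are
found by convolving the non-duct indicator with the sphere footprint
(FFT), keeping centres with zero overlap whose depth lies in 15–25 mm.
Depth is measured along the beam axis through the tumor centre column,
from the *outer* skin surface (air interface) to the upper face of the
shallowest tumor voxel — the illuminated surface is the dosimetric
reference, and "distance to the skin" is otherwise ambiguous.  The
shallowest site wins; ties break by lateral distance to the apex axis,
then lexicographic index.  Phantoms with no feasible site are marked
ineligible (a value, not an error).

## Monte Carlo light transport

A weighted-packet voxel Monte Carlo at 808 nm, written for heterogeneous
labelled media:

* **Sampling** — scattering lengths are drawn from μ_s alone
  (s = −ln u/μ_s) and absorption is handled continuously: along each
  traversed segment ℓ the packet deposits W(1−e^(−μ_a ℓ)) into the voxel
  and attenuates accordingly (microscopic Beer–Lambert weighting).  With
  μ_s = 0 this reproduces the Beer–Lambert law *exactly*, which is the
  validation route used by the tests; an analog-absorption scheme would
  only converge to it statistically.
* **Scattering** — Henyey–Greenstein by inverse CDF; g = 0 falls back to
  isotropic.
* **Interfaces** — unpolarized Fresnel reflection/refraction wherever the
  refractive index changes across a voxel face, including the ambient
  (n = 1) entry surface and grid exits.  The per-tissue indices
  (1.37–1.45) make internal mismatches physically meaningful; a flag
  disables all of it for Beer–Lambert validation.
* **Termination** — Russian roulette below weight 1e-4 with survival
  probability 0.1.  Roulette creates and destroys weight (unbiased in
  expectation, nonzero per run), so the ledger carries a net `roulette`
  term and conservation launched = absorbed + reflected + transmitted +
  roulette holds to 1e-6 on every run; violation raises.
* **RNG** — each packet owns an xorshift128+ substream seeded by
  splitmix64(seed, packet index): results are reproducible and
  independent of execution order.
* **Scoring** — fluence rate φ = A/(μ_a V), scaled so the source delivers
  irradiance × field area (default full entry face at 330 mW/cm²; disc
  and rectangle footprints available).  Air voxels (μ_a = 0) score zero.
  Every tissue has μ_a > 0, so the estimator is defined where it matters.
* **Units** — coefficients are cm⁻¹ at the API, converted once to mm⁻¹
  at the kernel boundary; geometry is mm; fluence is mW/cm².

Default optical properties at 808 nm (μ_a, μ_s in cm⁻¹; n; g): skin
1.35/196/1.37/0.9, fat 0.09/108/1.45/0.9, duct 0.06/114/1.42/0.9, tumor
with nanoparticles 0.48/98/1.45/0.9.  The tumor absorption is the 0.10
tissue baseline plus the 0.38 cm⁻¹ UCQR contribution (75 mg/kg loading).

## Singlet-oxygen dose

The cascade is ETE = ET1 × ET2 × ET3 with ET1 = 16.3 % (QD→Yb), ET2 =
f₅₄₀ × p_multi (540-nm pathway fraction 50 % times the multiphoton
excitation probability, swept over 20–100 % in 20 % steps), and ET3 =
75 % (Er→Rose Bengal), giving the canonical grid 1.2/2.4/3.7/4.9/6.1 %
after one-decimal half-up rounding (full precision is used internally).
ET2's dependence on excitation intensity is deliberately not modelled; a
constant ET2 per voxel tends to overestimate the dose in deep tumors.

**Dimensional note (important).**  A rate written as φ·ETE·γ/E₅₄₀ has
units of photons per *area* per time.  The quantity the threshold is
defined on is volumetric (photons/cm³), and the step "fluence absorbed by
the nanoparticles in each voxel" is precisely μ_a,UCQR·φ — the absorbed
power density.  The implemented per-session dose is therefore

    PD = μ_a,UCQR · φ · ETE · γ · t_session / E₅₄₀   [photons/cm³]

with μ_a,UCQR = 0.38 cm⁻¹, γ = 0.75 (the Rose Bengal singlet-oxygen
quantum yield; configurable, and every γ-dependent output records the
value used), t_session = 606 s and E₅₄₀ = hc/540 nm computed from CODATA
constants.  PD is jointly linear in φ, ETE, γ and t.  The dose is nonzero
only on tumor voxels: the nanoparticles accumulate there via the EPR
effect.  Oxygen is assumed non-limiting throughout.

## Treatment planning

Sessions are identical — optical properties do not change as voxels die —
so doses accumulate linearly and a voxel needs ceil(threshold/PD)
sessions; the whole-tumor count is the per-voxel maximum, and voxels with
zero per-session dose are reported explicitly as unreachable rather than
as a large integer.  Threshold comparisons use a 1e-12 relative epsilon
so that PD = threshold/n accumulated n times kills at session n despite
float rounding; "reaches the threshold" is ≥, a measure-zero choice made
for determinism.  Kill maps are nested across sessions by construction
and, because fluence decays with depth, death progresses from the tumor
top downward.

## Reporting conventions

One-decimal report values use half-up rounding (9.95 → 10.0, 10.85 →
10.9, 10.25 → 10.3), implemented via `decimal` with a pre-snap that
removes binary float noise.  Depth planes are voxel-aligned (thickness =
pitch) and labelled at the plane's upper face.  Rendered cross-sections
use fixed colormaps with the normalization recorded in a JSON sidecar, so
identical configs produce byte-identical images.

## Problem sizes

The test suite and examples run phantoms at 80–120³ voxels (26–40 mm) and
10⁵–10⁶ packets; the depth/efficiency sweep in the acceptance tests uses
a 120³ homogeneous fat + skin + duct-host phantom at 10⁶ packets per
depth (15/20/25 mm).  These sizes give per-voxel tumor fluence standard
errors of a few percent, which is sufficient for the arithmetic and
monotonicity properties being checked; absolute session counts on
synthetic phantoms depend on the minimum tumor-voxel fluence and are not
compared against any external value.  Full-scale 500³ cohort runs use the
same code paths with larger `shape` and `n_photons`.

## Known limitations

* Absolute session counts are sensitive to the deepest tumor voxel's
  fluence, which is the noisiest scored quantity; raise `n_photons`
  before trusting them.
* No oxygen-depletion kinetics, no photobleaching, no
  excitation-intensity-dependent upconversion, no re-emission transport
  (the 540-nm pathway transfers by resonance without propagating).
* Spherical tumors only; no fractionation schedules with varying beams.
* The synthetic generator's duct morphology is statistical, not
  anatomical.
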