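# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `striocomp`.  Everything quantitative
stated here is computed by the test suite or the example scripts.

## The analysis being modelled

Connectivity-based striatal parcellation classifies each striatal voxel by
the share of its probabilistic streamlines reaching a matrix-favoring
versus a striosome-favoring composite of ten extra-striatal "bait"
regions.  The two shares sum to one; a voxel is matrix-like at
`P(matrix) >= 0.55`, striosome-like at `P(striosome) >= 0.55`, and
indeterminate in the `[0.45, 0.55)` band.  Downstream measures are
compartment-like volumes (raw mm³ and the plain ratio volume/eTIV),
equal-volume high-bias masks (13% of striatal volume per compartment,
truncated to the smaller side when one distribution is poor), largest
26-connected cluster volumes, centroid-relative voxel locations (RAS
axes; rostral = +y, ventral = −z), radial diffusivity
((λ₂ + λ₃)/2 of the tensor eigenvalues), leave-one-bait-out somatotopic
zones with the ratio (V_dom − V_non)/(V_dom + V_non), covariate-adjusted
linear-model comparisons with step-up Benjamini–Hochberg correction inside
pre-declared families, and voxelwise Freedman–Lane permutation inference
with variance smoothing and TFCE.

Because the source cohorts for such analyses are access-restricted human
data, the package is exercised entirely on synthetic phantoms whose
compartment ground truth is known, which turns every pipeline stage into a
testable recovery problem.

## The phantom generator

One subject is a 66×46×36 grid of 1 mm isotropic voxels (RAS axes,
diagonal affine) holding:

* **Nuclei.** Caudate and putamen rasterized as ellipsoids per hemisphere,
  mirror-symmetric across the midline; ~2,940 striatal voxels in total.
  This is a desk-scale striatum: volumes are roughly one third of adult
  values so that full tractography of a subject takes seconds.
* **Compartment ground truth.** Striosome tubules are grown as
  direction-persistent random walks of single-voxel width.  A voxel may
  join a tubule only if all of its already-striosome 26-neighbors are
  among that walker's last two voxels; this keeps each tubule a
  non-self-adjacent chain (so a 2×2 cross-section can never form and the
  branch diameter equals the 1 mm voxel size, inside the 1.25 mm
  histological cap) and keeps distinct tubules ≥2 voxels apart, so they
  form separated components while the matrix stays contiguous.  Growth is
  gated by a rostroventral acceptance gradient (`location_bias`, default
  0.85) and seeds are drawn with a rostroventral bias (`seed_bias_beta`,
  default 2), reproducing the striosome's location bias; builds are
  rejected and regrown until the striosome fraction is within ±2
  percentage points of the 15% target, each hemisphere has ≥3 striosome
  components, and the striosome centroid sits ≥0.3 mm rostral and ventral
  of the matrix centroid.
* **Bait regions and wiring.** The ten bait regions are shell wedges
  17–20.5 mm from a per-hemisphere angular origin: five matrix-favoring
  wedges tile a dorsal polar cap (polar ≤ 50°) and five striosome-favoring
  wedges tile a rostral/lateral equatorial band (polar 90° ± 34°).  Wedge
  azimuths are occupancy quantiles of the striatal azimuth distribution,
  so the ten somatotopic sectors hold comparable striatal volumes (without
  this, sector sizes range over a factor of ~60 and no zone-recovery
  criterion can coexist with a zone-size bound).  Matrix efferents ascend
  vertically toward the cap; striosome efferents run horizontally toward
  their sector's wedge.  Each striatal voxel's orientation mixture puts
  `(1 − leakage) · zone_dominance` (defaults 0.85 · 0.8) on its own
  sector's axis, the rest of the same-affinity mass on the other four
  same-affinity axes, and the full `leakage` (0.15) on the voxel's
  opposite-affinity sector axis — which doubles as the through-fascicle
  that lets opposite-committed streamlines traverse the voxel.  Corridor
  (non-striatal) voxels carry two crossing fascicles, one vertical and one
  horizontal-radial.  Because the two fiber systems are orthogonal, the
  0.2-cosine curvature gate acts as a crossing-fiber selector: a
  streamline committed to one affinity can never be captured by fibers of
  the other, which is the phantom analog of the crossing-fiber resolution
  that makes compartment-specific tracking possible in real data.
* **Microstructure and covariates.** Tensor eigenvalue triples
  (1.0, 0.6, 0.4)×10⁻³ mm²/s with 5% lognormal voxel jitter (RD ≈
  5×10⁻⁴ mm²/s, a gray-matter-typical value), an eTIV analog of
  1.43×10⁶ mm³, and subject covariates (group, severity, scanner, study,
  age).

**Cohorts.** HC subjects are independent draws of the base phantom with
multiplicative lognormal jitter (σ = 0.03) on eTIV and nucleus volume.
MDD subjects additionally receive (a) a putamen volume scaling and a
rostral-putamen zone in which matrix-wired voxels are rewired toward
striosome-favoring targets — the zone size and the scaling are solved
jointly from the configured compartment-volume shifts (defaults −8.2%
matrix-like, +15% striosome-like) using the 85:15 ground-truth ratio — and
(b) a rostral-caudate zone, growing with severity score (Hamilton scale,
default 1.5% of caudate striosome wiring per point above 8), rewired in
the opposite direction.  Rewiring changes connectivity, not ground-truth
labels, mirroring the fact that the measured quantity is
connectivity-defined, not histological.  Severity scores are drawn
uniformly over 8–30 and binned with the three published scale tables
(overlapping printed bin edges resolved as half-open intervals).

## The tracker

Streamlines start at a uniformly jittered position in their seed voxel and
take 0.5 mm steps.  The first direction is drawn from the seed voxel's
mixture as stored (an efferent launch); in region-to-region mode the
initial orientation is additionally randomized (two-directional seeding),
which is why that mode's counts are normalized per seed volume.
Directions are re-sampled on entry into a new voxel — fields are piecewise
constant per voxel, so re-sampling every 0.5 mm step would only multiply
draws without adding information.  A re-drawn direction is antipodally
flipped when the flip better matches the previous step and accepted when
the cosine reaches the 0.2 curvature threshold; incompatible draws are
re-drawn up to `curvature_retries` times (default 16) before the
streamline is discarded.  The retry budget is what lets a streamline find
the locally compatible crossing fiber: with a single retry, any streamline
crossing an opposite-affinity voxel would die at its first draw of the
dominant (perpendicular) axis.  Streamlines terminate by first touch of a
target (credited), touching an avoid/exclusion mask, exiting the defined
field or the grid, or exhausting the 2,000-step budget (all discarded).
Nearest-voxel field lookup is used throughout — a deliberate deviation
from real-data trackers, which interpolate, justified by the piecewise
constant phantom fields.  The kernel is a single-threaded numba function
with an internal seeded RNG; identical parameters and seed give
bit-identical counts on any platform.

On the default phantom this machinery recovers the ground truth
essentially perfectly (voxel agreement 1.00 at 200+ samples per voxel;
recovered striosome fraction 15.0%), with bias probabilities concentrated
near 0.87/0.13 — far from the 0.55 threshold, which is why two
independent-seed parcellations at 2,000 samples per voxel differ in total
matrix-like volume by ≈0% (the acceptance script reports this against the
0.14% test-retest bound).

## Statistics

* **Scalar comparisons** are OLS fits (statsmodels) of each measure on the
  group indicator plus covariates of no interest (study, scanner, age;
  categorical ones expanded to indicators), with type-II F tests and
  percent differences of covariate-adjusted means.  Severity associations
  within the MDD subset use the same machinery with the score as the
  regressor of interest.
* **Multiple comparisons** use step-up Benjamini–Hochberg (statsmodels
  `fdr_bh`) within the pre-declared families (nucleus sizes, nucleus RD,
  the four compartment volumes, high-bias RD, the two caudate severity
  tests, zone ratios).  The output column is named `bh_adjusted`: BH controls the false
  discovery rate, and the column name says so even when the correction is
  used in an FWE role.
* **TFCE** integrates extent(h)^E · h^H dh with H = 2, E = 0.5,
  26-connectivity and 100 integration steps by default, with extents in
  mm³.  Thresholds are placed at midpoints (k − ½)·dh: strictly interior
  thresholds never coincide with the map maximum, making the discretized
  integral stable to last-bit rounding of the statistic (with endpoint
  thresholds, the entire top-threshold contribution can appear or vanish
  on a 1-ulp change).  Negative statistics are enhanced on the negated map
  and returned with negative sign.
* **Permutation inference** follows Freedman–Lane: nuisance effects are
  fitted, their residuals permuted, the nuisance fit added back, and the
  full-model t statistic recomputed; the residual-variance image is
  smoothed with a Gaussian of σ = 2 mm (interpreted as σ, not FWHM;
  configurable) before the t map is formed, and the TFCE-enhanced map is
  compared against the null distribution of its permutation maximum.  The
  identity permutation is included, so corrected p ≥ 1/n_perm.  An
  `exhaustive` mode enumerates all n! permutations for exact tests on tiny
  cohorts.  Cohort analyses run this on the striatal bounding box and
  re-embed the maps (TFCE labelling scales with grid volume; in-mask
  results are unchanged).

## What the tests show — and what they do not

The suite verifies the pipeline against independent brute-force oracles
(BFS-component TFCE, full permutation enumeration, closed-form
gambler's-ruin absorption for the tracker on a 1D chain, textbook step-up
BH), checks the type-I error of the permutation pipeline on 200 synthetic
null cohorts (the observed family-wise false-positive rate must fall in
the binomial 95% CI around α = 0.05), and demonstrates recovery of the
injected cohort effects at n = 20 + 20 with correct sign and location.
Reduced problem sizes are used throughout (2,000 samples per seed voxel
for the reliability analog, 150–500 elsewhere; 500 permutations; 25–100
TFCE steps); at the phantom's contrast these are well past convergence.

Passing these tests shows the *machinery* is correct, not that real
striatal tractography behaves this way.  The phantom omits, among other
things: scanner noise and the diffusion signal itself (fields are supplied
at the fitted-model level), registration error, partial-volume mixing
beyond single-voxel tubules, fasciculated striosome efferent bundles
(hence region-seeded, B-to-A matched-versus-mismatched contrasts are not
reproduced — compartment-seeded A-to-B contrasts are), distance-dependent
tractography attenuation, and any true biological coupling between
depression severity and anatomy — cohort effects are injected by
construction, so effect-recovery tests validate sensitivity, not
discovery.

## Parameter summary

| parameter | default | units | meaning |
|---|---|---|---|
| `striosome_fraction` | 0.15 | — | ground-truth striosome share of striatal volume |
| `striosome_diameter_cap_mm` | 1.25 | mm | maximum tubule cross-section |
| `leakage` | 0.15 | — | orientation mass toward opposite-affinity baits |
| `zone_dominance` | 0.8 | — | same-affinity mass on the sector-dominant axis |
| `curvature_threshold` | 0.2 | cos | minimum cosine between successive steps |
| `step_length_mm` / `max_steps` | 0.5 / 2000 | mm / — | streamline propagation budget |
| `samples_per_seed_voxel` | 5000 | — | streamlines launched per seed voxel |
| `curvature_retries` | 16 | — | re-draws before discarding a streamline |
| `min_total_count` | 10 | streamlines | classification floor per voxel |
| `bias_threshold` | 0.55 | — | compartment-like classification threshold |
| `high_bias target_fraction` | 0.13 | — | high-bias mask size as striatal share |
| zone `floor_percentile` / `size_bound` | 75 / 4 | — | influence floor; max zone size ratio |
| `n_perm` / `variance_smoothing_mm` | 5000 / 2 | — / mm | permutations; variance-smoothing σ |
| TFCE `H` / `E` / steps / connectivity | 2 / 0.5 / 100 / 26 | — | enhancement parameters |

Degenerate inputs fail loudly rather than silently: infeasible striosome
geometry names the violated constraint, empty seed masks, overlapping
masks, rank-deficient designs, constant outcomes and out-of-range
thresholds all raise with specific messages, and a zone whose region has
no influence support names the region.  An undefined zone ratio
(V_dom + V_non = 0) is reported as missing, never as 0.
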