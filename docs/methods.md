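# Methods

## Masks and geometry

A mask is a 3D boolean lattice with physical spacing (sx, sy, sz) in mm;
axis order is (x, y, z) in index space and z is the axial slice axis, the
axis along which humans page while editing. Loading binarizes at a
threshold (default 0.5, so 0/1, 0/255 and probabilistic-rounded sources
all map to {0, 1}); writing stores uint8 NIfTI-1 with a diagonal affine,
so load∘save is exact on voxels and float32-exact on spacing.

Two masks are *comparable* iff they share lattice dimensions and spacing
(relative tolerance 1e-5). Mismatched pairs raise rather than resample:
silent resampling would change the pixel-count metrics (APL, FNPL, FNV),
which are defined and reported in raw pixels. Rotational or shear
components of an affine beyond axis permutation/flip are ignored with a
warning flag: both masks of a pair live on the same grid, so a shared
rigid transform cannot change any inter-mask distance, and supporting it
would buy nothing but false generality.

## Boundaries

Two surface representations are computed from 6-connectivity (face
adjacency), with the lattice border counting as background so structures
clipped by the field of view still have a surface:

* **voxel-center**: one element per boundary voxel, position at the voxel
  center, weight = exposed face area. Used for Hausdorff and average
  surface distance, whose definitions speak of "every point in surface A".
* **face-surfel**: one element per exposed face, position at the face
  center, weight = face area (product of the two orthogonal spacings).
  Used for surface Dice, whose inputs are surface *areas*. Whether
  published surface-Dice values used area-weighted surfels or voxel counts
  is often unstated; both modes are exposed, face-surfel is the default,
  and the choice is recorded here precisely because the two differ on
  anisotropic grids.

Slice-wise 2D edges use 4-connectivity within each axial slice; a
structure one pixel thick is all edge. Nearest distances between boundary
sets are exact KD-tree queries (no sampling), and a deliberately
index-free all-pairs brute-force oracle ships alongside for testing; the
two agree to 1e-9 mm on every lattice the suite draws.

## Metric conventions

* Empty∩empty: DSC = JI = 1 (perfect agreement on absence — the formulas
  are 0/0 and the batch pipeline must stay total); exactly one empty mask
  gives 0. Surface metrics on an empty mask are undefined and raise (or
  yield NaN + a warning inside the batch panel).
* Percentile Hausdorff pools both directed nearest-distance sets into one
  ascending multiset, then takes the percentile with linear interpolation
  between closest ranks; p = 100 returns the exact maximum. The pooled
  (rather than max-of-directed) reading follows the usual "arrange all
  distances in ascending order" formulation; the alternative convention
  exists in the literature and would give systematically larger values.
* ASD is the unweighted average of the two directed mean distances — not
  the pooled mean. The two differ whenever the surfaces have different
  element counts; the test suite contains a configuration where they are
  7/3 vs 2.5 mm.
* APL counts corrected edge pixels not coinciding (exact index equality,
  no tolerance band) with auto edge pixels, slice by slice. FNPL
  additionally drops corrected edge pixels lying inside the auto
  foreground: such pixels can only arise where the correction erased auto
  voxels, and FNPL is defined to exclude shrink edits. Hence
  0 ≤ FNPL ≤ APL always, with FNPL = APL when nothing was erased and
  FNPL = 0 for a pure shrink. A 3D-boundary variant (`mode="boundary3d"`)
  exists for sensitivity analysis; slice-wise 2D is the default because
  corrections are made slice-wise and the counts are reported in pixels.

## Statistics

All tests are two-sided; α defaults to 0.05. Shapiro–Wilk is computed as
a logged gate for the nonparametric choice, never as a silent branch.
Conventions are pinned so p-values reproduce bit-for-bit:

* Spearman ρ = Pearson correlation of average ranks. For n ≤ 10 the
  p-value is an exact permutation tail over all n! orderings (enumerated
  in vectorised chunks; n = 10 means 3.6M permutations and runs in
  seconds); above that, the t approximation with n−2 degrees of freedom.
* Mann–Whitney U reports U = min(U₁, U₂); exact null distribution when
  n₁n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections (scipy's
  implementation behind the package's declared interface).
* Kruskal–Wallis uses tie-corrected H with a chi-square p-value. Post-hoc
  pairwise Mann–Whitney tests run only when the omnibus p < α, with
  Bonferroni adjustment (p·m capped at 1) applied within that post-hoc
  family only.
* Missing values: pairwise-complete deletion per test, with per-test n
  recorded in each result.

Simulated type-I error of both group tests at α = 0.05 sits within ±0.01
of nominal over 5000 null replicates (checked in the acceptance suite).
Note that Spearman measures monotone, not linear, association; the
correlation table is meaningful for any monotone metric–time
relationship.

## Synthetic cohorts

The generator emulates what an undertrained segmentation model does to a
smooth organ-scale structure. The corrected mask is a clean base shape —
ellipsoid, box, or a two-lobe "pair of lungs" — on a default 64×64×32
grid at (1, 1, 3) mm spacing, lung-CT-like anisotropy at desk scale. The
auto mask degrades it with spherical edits defined in mm (so anisotropy
flattens their voxel footprints correctly):

* *add-blobs* are centered on the base surface and carved out of the auto
  mask — boundary notches, because interior holes would be invisible to
  contour-length metrics and real under-segmentation happens at the
  boundary;
* *erase-blobs* are placed in the background band near the surface and
  added to the auto mask — spurious bulges;
* an optional uniform boundary shift dilates or erodes the auto mask by
  whole voxel steps.

Every changed voxel is recorded in a ledger, giving ground truth for FNV
and for "APL > 0 whenever an edit happened".

Correction times are `exp(log(intercept + slope·driver) + ε)`,
ε ~ N(0, noise_sd): lognormal noise keeps times positive and
right-skewed, as real correction-time distributions are. Defaults —
intercept 5 min (load/save overhead, about the floor of real recorded
times), slope 0.05 min per APL pixel, noise_sd 0.35 — put default cohorts
at median ~15–25 min, the scale of reported thoracic correction times.
The default cohort regime varies the edit *count* (1–12 blobs) while
holding total edited volume roughly constant (radius ∝ count^(−1/3)), the
regime in which contour-length metrics and volume-overlap metrics
genuinely disagree; under it, APL's |ρ| against time exceeds volumetric
DSC's by construction, and the acceptance suite verifies that recovery on
a 200-case cohort.

What the generator does *not* emulate: real lung anatomy or CT intensity,
inter-observer variability, spatially correlated model errors, or editing
tools (interpolation brushes) whose cost is sublinear in contour length.
Passing tests therefore show the metrics and the statistical machinery
are computed correctly and behave as designed under a controlled
generative model — not that any particular metric best predicts real
clinician time on real images.

## Problem sizes and numerics

The test suite runs oracle comparisons on lattices ≤ 16³ (where the
all-pairs oracle is exact and cheap), statistical calibration at 5000
replicates, and cohort recovery at 200 cases on the default grid — sizes
chosen so the full suite completes in about a minute on one CPU while
every check retains its power. Percentile and quartile computations use
numpy's linear interpolation; surface-Dice tolerance comparisons use ≤ τ
with exact arithmetic (coincident elements give exactly 0.0, so τ = 0 is
well-defined). Ties in ranks take mean ranks everywhere.

## Known limitations

* No sub-voxel surface interpolation (no marching cubes): surface
  positions are voxel-face or voxel-center, so distances are quantised at
  the spacing scale. On very coarse grids the surface Dice at τ smaller
  than the spacing is conservative.
* Masks must share a grid; no registration or resampling is provided, by
  design.
* The exact tie/continuity conventions behind any externally published
  p-value may differ from the ones pinned here; comparisons across
  implementations should compare conventions first.
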