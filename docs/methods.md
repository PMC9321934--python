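# Methods

`osteovasc` quantifies bone and blood-vessel microstructure
simultaneously from contrast-enhanced micro-CT volumes of small-animal
long bones. A specimen is imaged after perfusion with a radio-opaque
contrast agent (barium sulfate), which makes the vasculature the
brightest phase, mineralized bone intermediate, and marrow/background
dark. The pipeline turns one grayscale volume into a row of scalar
morphometric parameters, and a set of such rows into group-comparison
statistics. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic phantoms do and do not
demonstrate.

## Segmentation model

The three tissue classes are separated by a marker-controlled watershed.
Seeds come from hysteresis thresholding: per class, connected components
above a low intensity threshold are kept when they contain at least one
voxel above the corresponding high threshold. Default thresholds derive
from a four-class Otsu multithreshold (background, marrow, bone,
vessel); each raw Otsu cut is re-centered in the intensity gap it falls
in, which is a no-op on continuous histograms but keeps the hysteresis
bands non-empty on near-discrete ones. Bright voxels within two voxels
of a vessel seed are excluded from the bone seeds: they are
partial-volume halo at the vessel wall, and leaving them unseeded lets
the watershed place the weak bone/vessel boundary instead of freezing it
at the seed stage.

The watershed floods a control surface built from the **phase asymmetry
of the 3D monogenic signal**. Per scale *s*, the volume is band-passed
with an isotropic log-Gabor filter (center wavelength *s*, bandwidth
ratio 0.55); the even response e_s is the filtered signal and the odd
response o_s the magnitude of its Riesz transform; the map is

    PA = Σ_s max(|o_s| − |e_s| − T, 0) / (Σ_s √(e_s² + o_s²) + ε)

clipped to [0, 1], with T a noise floor (`noise_factor` × the
Rayleigh-corrected median amplitude at the finest scale) and ε a small
amplitude-relative constant. Because T and ε scale with the signal, the
map is invariant to rescaling the intensities — the property that makes
it a better barrier than a gradient magnitude at the low-contrast
bone/vessel interface. Defaults: wavelengths {4, 8, 16} voxels
(capillary-to-trabecula edge widths at 3.5 µm voxels), `noise_factor`
2.0. A note on magnitudes: at an ideal between-voxel step the odd
response is only twice the even one, so the face value of PA saturates
near 0.45, not 1; what matters for the watershed is that faces out-score
plateaus, which the noise floor guarantees.

A small tie-break term, 0.02 × the min-max-normalized intensity, is
added to the control surface before flooding. PA is flat inside each
phase, and priority-queue tie-breaking by insertion order would
otherwise dilate every bright structure by about one voxel; the bias
resolves plateau ties toward the darker phase and is two orders of
magnitude below the PA scale, so genuine barriers are unaffected. On a
blur-free, noise-free phantom the full chain reproduces midpoint
thresholding exactly.

## Vascular enhancement and leak removal

Incomplete perfusion ruptures vessels and pools contrast in the marrow.
The pools are removed with a multi-scale Hessian line filter
("tubeness"): per scale σ, eigenvalues λ1 ≥ λ2 ≥ λ3 of the
Gaussian-derivative Hessian give the single-scale response
σ²·√(λ2·λ3) where λ2, λ3 < 0 and 0 otherwise; the σ² factor equalizes
scales and the multi-scale map is the plain sum (defaults σ ∈ {1, 2, 4}
voxels, i.e. calibers of roughly 7–28 µm at 3.5 µm voxels). Core voxels
are the top `keep_fraction` (default 0.05) of the in-mask response;
the cleaned mask is the morphological reconstruction (26-connectivity)
of the vessel mask from those cores. A connected vessel run therefore
survives end-to-end, while a detached pool whose maximum response misses
the core set vanishes. The core quantile must sit above the blob
response: blobs at the caliber of the filtered band score within a
factor 1.3–2 of equal-radius tubes (the closed-form Gaussian-Hessian
ratio), so a permissive quantile would never remove anything. At 0.05
the cutoff is carried by vessel-axis voxels and clears every detached
pool in the phantom studies. Known limitation: a contrast pool the size
of a mid-caliber vessel is physically indistinguishable from a vessel
to a pure line filter; removal relies on pools being larger than the
tuned caliber band, which matches extravasation pools but not
micro-leaks.

The cleaned vasculature is partitioned by local thickness into
capillaries (< d1), sinusoids, and arteries/veins (> d2), with
d1 = 10 µm and d2 = 30 µm by default — the literature gives the three
classes qualitatively but no printed cutoffs, so both are mandatory
config entries in reports. Per 26-connected component, when the
interquartile range of thickness lies inside one class band, the
component is collapsed to its majority class.

## Compartments

The total volume TV (everything inside the outer cortical contour) is
built from per-keyslice 2D convex hulls of the bone mask (default every
50th transverse slice, plus the last), with the in-between slices
interpolated by linearly blending the signed distance maps of the
bounding hulls and thresholding at zero. Slice-wise hulls rather than
one 3D hull: a 3D hull would bridge the metaphyseal flare and the shaft
curvature and inflate TV.

The marrow cavity is found by eroding the TV inward until the cortical
shell is passed. Per slice, voxels are binned into one-voxel depth
rings from the TV boundary; the shell is the run of rings that are
mostly bone (fraction ≥ 0.5), and the cavity boundary is placed at the
sub-voxel depth where the ring bone-fraction crosses 0.5 (linear
interpolation between rings). The cavity is the largest 6-connected
component of the per-slice result and contains the trabecular bone
inside it. The split is then set algebra: trabecular = bone ∩ cavity,
cortical = bone \ cavity, so voxel counts are exactly additive.

## Morphometry

* **Volume fractions** are voxel-count ratios: BV/TV and VV/TV against
  the TV envelope, Tb.BV/Mar.V against the marrow cavity.
* **Local thickness** follows the maximal-inscribed-sphere definition:
  the thickness at a voxel is the diameter of the largest sphere
  containing it that fits in the structure. Spheres are centered on
  foreground voxels with radius d − ½ (d = Euclidean distance to the
  nearest background center; the half-voxel offset puts the sphere
  boundary at the structure surface, so a 5-voxel slab reads 5.0), and
  a voxel belongs to a sphere when its center is within half a voxel of
  it. The map is exact under this convention: all centers are
  considered, pruned only when provably dominated by a neighbor
  (d(n) ≥ d(c) + |n−c|). Digital cylinders read ≈ 7% under their
  continuous diameter — for curved surfaces the nearest background
  center lies essentially on the continuous surface — which is a
  property of voxelization, not of the estimator; the test suite pins
  the estimator to a brute-force maximal-sphere search instead of to
  continuous values. Mean thickness is the unweighted average over
  structure voxels, reported in µm.
* **Fractal dimension** is the box-counting slope: the 6-adjacency
  boundary voxels of the mask (or the voxel set itself, for sets that
  are already lower-dimensional) are overlaid with cube grids of sizes
  {1, 2, 4, 8, 16} anchored at the volume corner, partial boxes
  counting; FD is the negated slope of the least-squares fit of
  log N(λ) on log λ. No grid-offset averaging: a single origin keeps
  counts reproducible and suffices for the fit quality required
  (R² ≥ 0.98 on reference sets).
* **SMI** uses the Steiner-formula expression 12·V·M/S². The surface is
  the 0.5 level of the σ = 1 voxel Gaussian-smoothed mask, triangulated
  by marching cubes after padding with one background layer; V is the
  enclosed volume, S the triangle area, and M the integral of mean
  curvature ½·Σ_e ℓ_e·α_e over mesh edges with signed exterior dihedral
  angles. Faces within one voxel of the original volume border — the
  sealing faces the padding creates plus the smoothing-rounded rim next
  to them — are excluded from S and M (standard volume-of-interest
  boundary correction; without it, a slab clipped by the grid acquires
  an artificial rim term 6πt/a and never reaches the plate limit 0).
  Reference values: sphere 4, long rod 3, wide plate 0; a finite capsule
  of length 40 r evaluates to 3.09 analytically, hence the ±0.2
  tolerance used in the tests.
* **Connectivity density** comes from the Euler characteristic χ by
  2×2×2 octant counting (26-connected foreground). With β0 the number
  of foreground components and β2 the number of enclosed cavities
  (6-connected background components not touching the border), the
  connectivity is β1 = β0 + β2 − χ and Conn.D = β1 / TV, reported per
  mm³.

## Statistics

Per parameter and per group: Lilliefors normality (KS distance against
a normal with estimated moments; p-value from a cached, seeded
Monte-Carlo null with 10 000 replicates — no table interpolation) and a
two-sided Grubbs outlier test applied once, flag-only. Across groups:
Bartlett's test, one-way ANOVA with η² = SS_between/SS_total labelled
by Cohen's benchmarks as lower bounds (≥ 0.14 large, ≥ 0.06 medium,
≥ 0.01 small), and Tukey HSD (Tukey–Kramer under unequal n) only when
the ANOVA p-value is below α = 0.05. Normality or homoscedasticity
violations are recorded in the report but do not switch the test, and
flagged outliers are not removed — the analysis stage mirrors a
conventional fixed protocol and leaves robustness decisions to the
reader of the report.

## Synthetic phantoms

The phantom generator provides ground-truth-exact stand-ins for the
scans: a cortical shell (hollow cylinder along z, outer radius 180 µm,
wall 35 µm by default at 3.5 µm voxels), a trabecular lattice of
disc-shaped plates and capsule rods filling a target fraction (default
0.15) of the metaphyseal marrow with a plate/rod volume mix
(`trabecular_mix`), a binary-branching vascular tree of capsules (root
radius 30 µm, radius decay 0.7 per level, six levels so the tree spans
arteriole-to-capillary calibers, branch angles uniform in 20–60°),
optional spherical contrast pools seeded on — or offset perpendicular
from — the vessel surface, and optional spherical osteolytic carving of
the lattice. Rendering assigns the four intensity levels
(20/60/140/220), applies a Gaussian blur (σ = 0.8 voxels) as the only
partial-volume model, and adds white noise (SD 8, i.e. 10% of the
bone–marrow gap). Macro-geometry and noise are driven by separate seeds
so one specimen can be re-imaged with fresh noise. Grouped studies
reproduce an 8-group design (two time points × four treatments,
10/14/10/11 and 7/7/7/7 animals), with per-animal lognormal jitter
(CV 0.08) on the trabecular fill and vessel root radius and
group-level effect multipliers on any numeric parameter.

What the phantoms do not emulate: reconstruction artifacts (rings,
phase fringes, beam hardening), anisotropic resolution, intensity
inhomogeneity, the true anatomy of the metaphyseal flare (the cortex is
a straight cylinder), and textured marrow. Passing the phantom suite
therefore demonstrates the correctness of the algorithms under the
stated imaging model, not segmentation accuracy on any particular
scanner's data; on real volumes the automatic thresholds and the PA
noise floor are the knobs to revisit first.

## Problem sizes and determinism

The test suite runs phantoms at 96³–128³ and the full 73-animal study
at 96³; these sizes preserve every geometric regime of the method
(shell, lattice, multi-caliber tree) at roughly 15–30× fewer voxels
than a full acquisition. Everything is deterministic given the seeds:
phantom generation, FFT-based filtering, watershed flooding (fixed
raster tie-break), and the Monte-Carlo nulls (fixed internal seed,
cached per sample size).
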