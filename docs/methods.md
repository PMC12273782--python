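# Methods

This note documents the models and procedures implemented in `tbi3d`, the
parameters that matter, the numerical choices, and what the synthetic
phantom does and does not establish about real data.

## Coordinate and unit conventions

Rasters are `(z, y, x)` indexed, 0-based; the physical coordinate of a
voxel is `index × spacing + origin`, with spacing and all internal
distances in μm.  Reported volumes are mm³ (1 mm³ = 10⁹ μm³) and lengths
mm.  The left–right axis defaults to the last array axis, with the injured
(ipsilateral) hemisphere on the positive side of the midsagittal plane.
Multi-resolution policy: each analysis runs at its own downsampling (coarse
for the lesion, medium for biomarker signals, fine for vessels); all three
factors are configuration fields, and desk-scale phantoms run at factor 1.
Downsampling is block-mean (it preserves the intensity normalization that
thresholding relies on); trailing partial blocks are averaged over present
voxels so border tissue is not discarded.

## Lesion segmentation

The lesion model assumes the two hemispheres are near mirror images, so
tissue missing unilaterally can be found without an atlas:

1. **Tissue segmentation.** Intensity threshold on the
   autofluorescence-carrying channel (Otsu when set to `auto`), keeping the
   largest connected component.
2. **Surface solidification.** Morphological closing with a Euclidean ball
   of physical radius (default 300 μm, configurable), then hole filling.
   The closing is computed through the distance transform (dilate =
   distance-to-mask ≤ r, erode = distance-to-complement > r), which is
   exact for the spherical element, anisotropy-aware and O(n); the volume
   is zero-padded past the dilation radius so the border never truncates
   the erosion.  A surface cavity is bridged when its mouth half-width is
   below the closing radius — and *absorbed into the solid* when bridged,
   so for lesion detection the closing radius must stay **below** the
   expected cavity mouth half-width.  The radius is therefore a
   smoothing/denoising scale, not a cavity-filling scale.
3. **Midsagittal plane.** Centre of mass of the solid mask along the
   left–right axis (fractional voxel index).
4. **Mirror–register–subtract.** The contralateral half is reflected about
   the plane (flip plus subvoxel linear shift so the reflection axis is
   exactly the fractional plane position), rigidly aligned to the
   ipsilateral half by the integer translation maximizing overlap (FFT
   cross-correlation over the ±10-voxel window — identical to exhaustive
   search), and subtracted: lesion = mirrored ∧ ¬solid, restricted to the
   ipsilateral side.  Registration is translation-only; the mirror
   hypothesis itself breaks down under rotation, and near-symmetric brains
   need none.  Components below 10⁻³ mm³ (configurable) are discarded; this
   minimum-size filter plus the side restriction stands in for manual mask
   refinement and is not claimed equivalent to it.

For sham-like brains with an empty lesion mask, the layering seed can fall
back to the tissue surface under a user-supplied craniotomy-window mask;
with neither, the boundary is empty.

## Conformal depth layers

Layer `k` is the set of tissue voxels (outside the lesion) whose distance
to the seed set — lesion ∪ its 6-adjacent tissue boundary — lies in
`[k·t, (k+1)·t)` μm, with t = 100 μm and 10 layers by default.  The primary
construction bins the Euclidean distance transform (exact continuous
distance, anisotropy-aware, O(n)); the reference construction iterates
binary dilation with a rasterized sphere of `floor(t / spacing)` voxels
(18 voxels per 100 μm at 5.37 μm spacing; a voxel joins when its centre is
within the radius, ties included).  The two constructions agree with
per-layer Jaccard ≳ 0.97 on full shells; iterated dilation accumulates up
to a voxel of rounding per iteration, so agreement degrades for shells
clipped to thin crescents at the tissue margin.  Layers are pairwise
disjoint, contiguous in depth, and their volumes sum exactly to the covered
tissue volume.

## Vascular quantification

**Vesselness.** The multi-scale Hessian filter with eigenvalues
`|λ₁| ≤ |λ₂| ≤ |λ₃|`, ratios `R_A = |λ₂|/|λ₃|` (plate vs line),
`R_B = |λ₁|/√|λ₂λ₃|` (blob), structureness `S = √(λ₁²+λ₂²+λ₃²)`, combined
as `(1−e^{−R_A²/2α²})·e^{−R_B²/2β²}·(1−e^{−S²/2c²})`, zeroed where λ₂ or λ₃
is positive (bright tubes), σ²-normalized and maximized over scales.
Defaults: α = β = 0.5; c adaptive at half the maximum Hessian norm; scales
3–24 μm spanning capillary-to-venule radii.  Implementation:
`skimage.filters.frangi`, behind this module's surface.  Near-isotropic
voxels are required (scales are converted at the mean spacing); resample
anisotropic data first.

**Segmentation.** Vesselness threshold (default 0.2, always
configuration-exposed — the response profile has a soft halo outside the
tube wall, so the threshold trades false wall voxels against gap
sensitivity) plus a minimum-component-volume filter.

**Skeleton graph.** 3D topological thinning to a one-voxel centerline;
nodes are skeleton voxels carrying the distance-transform radius, edges
join 26-neighbours with physical step length (s, s√2, s√3 for isotropic
spacing).  The mask is edge-padded past its thickest structure before
thinning so vessels touching the volume border keep their full centerline
(thinning otherwise retracts tube ends by ~2 voxels and loses transpose
invariance there).  Degree classifies endpoints (1), through nodes (2) and
branch points (≥3).

**Metrics.** Each edge is assigned to the layer containing its midpoint —
an unambiguous partition whose assignment error is bounded by one edge
length.  Layer length density = Σ edge lengths / layer tissue volume
(mm/mm³; the field has no single convention for length-density units, so
they are stated on every output).  Layer vessel volume = Σ π·r̄²·ℓ with r̄
the mean of the two node radii, excluding branch-node radii (the distance
transform overestimates at junctions) — divided by tissue volume (mm³/mm³).
A layer with vessel content but zero tissue volume reports NaN with a
warning, never infinity.

**Accuracy on digital cylinders** (radius 2–8 voxels, axis-aligned and
45°-oblique): centerline length within 2% of the analytic extent, raw EDT
radius within 0.5 voxel, frustum volume within 15% of πr²L for radii
≥ 3 voxels.  At 2-voxel radius the frustum error reaches ±25% and is
irreducible from integer centerlines: the wall is sampled by ~4 voxels and
the skeleton node is quantized up to half a voxel off-axis, and corrections
that fix the axis-aligned bias double the oblique one.  Two-voxel vessels
are at the resolution floor; radius and length remain reliable there, the
squared-radius volume does not.

## Signal quantification

Per brain and channel, the background threshold is the linear-interpolation
99.9th-percentile of intensities in the contralateral tissue (for Gaussian
background this sits at μ + 3.0902σ, giving a 10⁻³ false-positive
allowance).  The comparison is strictly greater-than, so a constant
background yields zero signal.  Supra-threshold tissue voxels pass a
minimum-component filter (default 10⁻⁴ mm³) standing in for an otherwise
unspecified denoising step — an approximation, flagged as such.  The layer
metric is supra-threshold volume over layer tissue volume.  Thresholds are
never shared across brains.

## Group statistics

Observations are one value per animal per layer, compared across groups
within each layer (pooling layers would erase the depth structure the
pipeline exists to measure).  Pipeline order: 1.5×IQR outlier removal per
group (linear-interpolation quartiles, closed fences so boundary values and
all-identical groups are retained; fewer than four values pass through
unchanged — note the procedure is one-pass by construction, not idempotent
on arbitrary data), then one-way ANOVA (classical between/within
decomposition), then Fisher's LSD using the pooled MS_within with
within-group degrees of freedom, unadjusted for multiplicity by definition.
Zero within-group variance with unequal means reports p = 0 with a warning;
fully degenerate data raises.  Significance level 0.05 throughout.

Cohort-level testing covers the four normalized comparison metrics (vessel
length density, vessel volume fraction, hypoxia and extravasation
fractions).  The per-layer tissue volume (the denominator) and the
whole-brain lesion volume are excluded by default: under the phantom's
noise-only variability they are quantization-deterministic, so one-voxel
differences would masquerade as p ≈ 0 significance.  They can be tested
explicitly via the `test_metrics` argument — real cohorts have the
inter-animal geometric variance the phantom deliberately lacks.

qPCR fold changes use group-mean ΔΔCt for the point estimate
(ΔCt = Ct_target − Ct_reference per animal, ΔΔCt = mean difference vs the
control group, fold change = 2^−ΔΔCt) and a two-tailed unpaired t test on
the per-animal ΔCt values; a per-animal-ΔΔCt variant would shift only the
descriptive spread, not the test, and is not the default.

## The phantom: what it emulates and what it does not

The generator emulates the statistical structure the pipeline assumes: a
bilaterally symmetric tissue ellipsoid with autofluorescent background and
Gaussian sensor noise; a recursive bifurcating vessel tree (radius ratio
0.75 per branching, deflection 20–60°, termination at 1.5 voxels radius or
at the tissue surface) rasterized by exact point-to-segment distance; an
ellipsoidal cavity opening to the dorsal surface; and
hypoxia/extravasation signal decaying as `exp(−d/λ)` from the lesion
surface (λ = 150 μm default — in real injured brains the observation is
only that signal concentrates near the injury, so the exponential is a
modelling choice that lets tests place known signal volumes in known
layers), zeroed
contralaterally beyond 3λ.  Every output is bit-reproducible from the seed;
the vessel tree can be seeded separately from the noise so cohorts can
share anatomy while varying acquisition noise.

Ground truth is computed independently of the pipeline's raster path:
cavity volume by 2× supersampled midpoint integration of the
ellipsoid-intersection; vessel totals analytically from the segment list;
per-depth-bin vessel quantities by exact point-to-ellipsoid-surface
distance of segment midpoints (Lagrange root-finding); "true" signal volume
as the region where the noiseless signal exceeds 3.0902 × noise sd,
matching what a 99.9th-percentile background threshold can recover.

The phantom does **not** model optics (point-spread function, light-sheet
shadowing, attenuation with depth), clearing artefacts (the ~10% iDISCO
shrinkage, which the pipeline sidesteps by comparing only batch-processed
brains), anatomically realistic geometry, hemodynamics, or inter-animal
variability beyond noise.  Passing phantom tests therefore establishes the
*computational* correctness of each stage under the stated model — exact
layer bookkeeping, unbiased lesion recovery for open cavities, calibrated
thresholds — not robustness to real-tissue imaging physics.

## Problem sizes and defaults used in verification

Verification runs use desk-scale volumes chosen to exercise every code
path: 128³ voxels at 5 μm for layer-construction equivalence; ~710k-voxel
brains at 15 μm for lesion recovery (5 seeds); ~155k-voxel brains at 20 μm
for the end-to-end cohort experiments (two groups of three brains, 20
repetitions for the null calibration and the programmed 2× vessel-density
effect; the acceptance script reports a 5-repetition version of the same
experiment).  The cohort phantoms use a 150 μm closing radius against a
400 μm cavity mouth, four 100 μm layers, and Frangi scales 15/30 μm matched
to the 25 μm root vessels.
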