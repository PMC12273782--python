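# tbi3d

Whole-brain 3D pathology quantification for traumatic brain injury (TBI).

After a controlled cortical impact, the damage around the contusion is not
uniform: vessel loss, hypoxia and blood–brain-barrier leakage are strongest
at the lesion rim and fade with distance into the surrounding cortex.
`tbi3d` quantifies exactly that spatial structure in cleared, light-sheet
imaged mouse brains, without registering to an atlas.  It is written for
researchers analysing multi-channel volumetric fluorescence data: a vessel
channel (lectin), an extravasation channel (70-kDa dextran, which also
carries tissue autofluorescence) and a hypoxia-marker channel.

## What it computes

1. **Lesion segmentation by mirrored-hemisphere subtraction.**  Tissue is
   thresholded (Otsu by default), the outer surface is solidified by
   spherical morphological closing, the brain is bisected at the
   centre-of-mass sagittal plane, and the mirrored contralateral hemisphere
   is registered (translation) to the injured one and subtracted.  The
   residual — what the intact side has and the injured side lacks — is the
   lesion mask, reported in mm³.
2. **Conformal depth layers.**  Disjoint tissue shells at
   `[k·t, (k+1)·t)` μm from the lesion boundary (default t = 100 μm, 10
   layers), computed by Euclidean-distance-transform binning, with iterated
   spherical dilation (100 μm ≈ 18 voxels at 5.37 μm spacing) as the
   reference construction.
3. **Vascular network metrics.**  Vessels are scored with the multi-scale
   Hessian (Frangi) vesselness filter
   `V = (1−e^{−R_A²/2α²})·e^{−R_B²/2β²}·(1−e^{−S²/2c²})`, thresholded,
   skeletonized to a centerline graph with per-node radii from the distance
   transform, and reported per layer as length density (mm/mm³) and volume
   fraction (mm³/mm³, frustum sum π·r̄²·ℓ over edges).
4. **Hypoxia / extravasation fractions.**  Per brain and channel, the
   threshold is the 99.9th percentile of intensities in the uninjured
   contralateral hemisphere; the metric per layer is the supra-threshold
   volume over the layer's tissue volume.
5. **Group statistics.**  1.5×IQR outlier removal per group, one-way ANOVA
   per metric per layer, Fisher's LSD post hoc, and qPCR relative
   expression by `2^{−ΔΔCt}` with unpaired two-tailed t tests on per-animal
   ΔCt.

A **synthetic phantom generator** (`tbi3d.phantom`) produces ground-truthed
brains — a bilaterally symmetric tissue ellipsoid, a branched bright-tube
vascular tree, a unilateral surface-opening cavity, perilesional signal with
exponential depth falloff, and Gaussian noise — so every stage can be
validated against analytic truth without animal data.

## Worked example

```python
from tbi3d import PhantomSpec, rasterize_phantom
from tbi3d.pipeline import PipelineConfig, analyze_brain

spec = PhantomSpec(
    brain_semi_axes=(500, 600, 800), spacing=(15, 15, 15),
    root_radius=25, min_radius=10, branching_depth=3, branch_length_um=350,
    lesion_center=(450, 0, 350), lesion_semi_axes=(250, 250, 250),
    noise_sd=10, seed=7,
)
vessel, extrav, hypoxia, tissue, truth = rasterize_phantom(spec)

cfg = PipelineConfig(lesion_factor=1, signal_factor=1, vessel_factor=1,
                     closing_radius_um=150.0, n_layers=4,
                     vessel_scales_um=(15.0, 30.0))
res = analyze_brain(vessel, extrav, hypoxia, cfg, brain_id="demo")
print(f"true lesion volume:      {truth.lesion_volume_mm3:.4f} mm^3")
print(f"recovered lesion volume: {res.lesion.lesion_volume_mm3:.4f} mm^3")
```

prints

```
true lesion volume:      0.0289 mm^3
recovered lesion volume: 0.0274 mm^3
```

and `res.metrics` holds the per-layer table:

```
metric        hypoxia_fraction  extravasation_fraction  vessel_length_density  tissue_volume_mm3
layer_min_um
0.0                     0.9878                  0.9875                 9.9803             0.0507
100.0                   0.1841                  0.1862                20.4662             0.0770
200.0                   0.0000                  0.0000                 7.7855             0.1077
300.0                   0.0000                  0.0000                 1.5108             0.1356
```

Read it as: the 0–100 μm shell next to the cavity is almost entirely
hypoxic/leaky (fraction ≈ 0.99 — the phantom places its strongest signal
there), the 100–200 μm shell is partially affected (≈ 0.18), and beyond
200 μm the signal is indistinguishable from the contralateral background.
Vessel length density is in mm of centerline per mm³ of layer tissue.  The
lesion volume is recovered within ~5% of the generated truth.

## Command line

```bash
tbi3d phantom --config spec.yaml --out brain1/       # synthetic brain + truth.json
tbi3d lesion  --channel extrav.nrrd --out lesion.nrrd --report lesion.json
tbi3d layers  --lesion lesion.nrrd --tissue tissue.nrrd --thickness 100 --n 10 --out layers.h5
tbi3d vessels --channel vessel.nrrd --layers layers.h5 --out vessels.csv
tbi3d signal  --channel hypoxia.nrrd --layers layers.h5 --contralateral contra.nrrd --out hypoxia.csv
tbi3d run     --config cohort.yaml                   # full multi-brain pipeline
tbi3d stats   --metrics out/cohort_metrics.csv --out stats.csv
```

Volumes are read/written as multi-page TIFF, NRRD or flat HDF5 (dataset
`volume`, spacing in the `spacing_um` attribute); metric tables are CSV.

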