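# Methods

## Overview

CompositIA estimates seven body-composition indices from a single
thoraco-abdominal CT volume in three stages:

1. **Level localization.** The volume is reoriented to RAS+ (axis 2 =
   inferior→superior), resampled to isotropic voxels and reduced over
   the right–left axis to a 2D sagittal projection. Three Hounsfield
   windows — [1000, 2000], [400, 500], [800, 1900] HU — are applied and
   stacked as channels, each linearly rescaled to [0, 1], and the image
   is resized (anti-aliased) to 128 (anterior–posterior) × 256
   (inferior–superior) pixels. A MultiResUNet regresses a heatmap whose
   training target places unit impulses at the L1 and L3 centers,
   filters with an isotropic Gaussian of σ = 15 px, and renormalizes so
   the global maximum is 1. At inference the two most intense local
   maxima are the predicted centers; the superior peak is L1. The pixel
   → voxel transform of the projection maps each peak to an axial slice
   index.
2. **Slice segmentation.** The axial slice at the predicted L1 level is
   windowed to [-1024, 500] HU and segmented by a 3-class U-Net
   (background / trabecular / cortical). The L3 slice is windowed to
   [-1024, 2048], [-190, -30] and [40, 100] HU (full contrast, fat,
   muscle), stacked as three channels, and segmented by a 4-class U-Net
   (background / SMA / VAT / SAT). Both heads are a single channel
   softmax, so classes are mutually exclusive; masks are the per-pixel
   argmax with ties resolved toward the lower class index.
3. **Index quantification.** Areas are `pixel count × sx × sy / 100`
   (cm²); density statistics are computed on the original HU slice,
   never on windowed values. The seven indices are L1 trabecular BMD
   mean and standard deviation (HU), L1 trabecular area (cm²), L3 SAT,
   SMA and VAT areas (cm²), and L3 SAT density standard deviation (HU).
   The cortical class contributes to no index.

## Model architectures

The environment this package targets is a plain scientific Python
stack, so the networks run on a small reverse-mode autodiff engine
(`compositia.nn`) written on numpy: same-padding 3×3/1×1 convolutions
via im2col GEMMs, 2×2 max pooling, exact stride-2 transposed
convolutions, batch normalization, channel softmax and sigmoid. Every
operation's analytic gradient is tested against central finite
differences.

* **MultiResUNet** (localizer): 4 encoder and 4 decoder MultiRes
  blocks joined by residual paths with 4/3/2/1 conv blocks at
  successive depths. A MultiRes block chains three 3×3 convolutions
  (emulating 5×5 and 7×7 receptive fields), concatenates the three
  feature maps and adds a 1×1 shortcut; block widths follow the
  W = 1.67·U split into 1/6, 1/3, 1/2 fractions. Output head is a 1×1
  convolution with sigmoid.
* **U-Net** (segmenters): 4-level encoder–decoder with double
  conv-BN-ReLU blocks, channel widths (f, 2f, 4f, 8f, 16f), up-conv
  decoder and softmax head.

Spatial inputs must be divisible by 2⁴.

## Training

Losses: pixelwise MSE for heatmap regression; cross-entropy plus soft
Dice for segmentation (robust to the small-foreground imbalance of the
cortical shell). Optimizer Adam; all shuffling and initialization are
seeded, so training is bit-reproducible. Optional early stopping
monitors a held-out fraction of the training subjects.

Heatmap training applies a seeded rigid-shift augmentation per batch
(±4 px anterior–posterior, ±8 px inferior–superior, projection and
target translated together, zero-filled borders). Without it the
landmark model can lean on the absolute grid position of L1 in the
training population and mistake a neighboring vertebra on subjects
near the edges of that distribution; the augmentation forces it to
use the image cue (the last ribbed vertebra) instead.

Defaults used at phantom scale (one CPU): localizer with 4 base
filters, 20 epochs, batch 4, lr 2·10⁻³; segmenters with 8 base
filters, 40 epochs, batch 4, lr 2·10⁻³. These sizes are deliberate
package choices so that the full study — 80 phantoms, three models —
trains in minutes; the architectures and every preprocessing constant
are unchanged at clinical scale, where one would raise the filter
counts and epochs by configuration.

## Phantom study conditions

The generator renders an elliptical body (air background −1024 HU)
containing, outside-in: a subcutaneous fat ring, an abdominal muscle
wall, a visceral cavity with organ-density background, visceral fat
columns, and a posterior vertebral column of cylindrical bodies — a
cortical shell (N(1200, 150) HU) around a trabecular core
(N(160, 30) HU) — separated by disc gaps. Fat is N(−100, 20) HU
clipped to [−190, −30]; muscle N(55, 12); organ N(30, 15); disc
N(80, 15); global acquisition noise N(0, 10) HU is added everywhere.
Default geometry is 96×96×120 voxels at 2 mm isotropic; population
variation samples body radii (30–40 × 24–31 voxels), SAT thickness
(4–8), muscle wall (3–5), spine radius (7–10), vertebra height (10–13),
disc gap (3–4) and the L1 level (0.58–0.66 of the superior–inferior
extent).

Vertebrae superior to L1 carry short rib stubs of cortical bone that
extend anterior to the column, so they remain visible in the sagittal
maximum-intensity projection. This reproduces the anatomical cue that
defines the level in real scans (L1 is the first rib-free vertebra):
without it, the phantom's vertebral bodies are indistinguishable and
the L1/L3 labels would not be identifiable from the image at all.

The spine sits posteriorly (up to 0.55 of the body's anterior–
posterior radius) but its offset is reduced when necessary so the
vertebra never touches the muscle wall or the fat ring; geometry draws
that cannot satisfy this are rejected and resampled. This keeps the
~1200 HU cortical shell away from the soft-tissue compartments, where
a single misclassified boundary pixel would otherwise dominate a
region's density standard deviation — a brittleness of crisp-boundary
phantoms that real CT, with its partial-volume blur, does not share in
the same degree.

L1–L3 separation is two vertebral pitches (~28 voxels ≈ 60 px on the
256-pixel grid), comfortably above both the 2σ minimum peak separation
and the 3σ distinctness bound for σ = 15, so the published σ is used
unchanged on phantoms.

What the phantom does **not** emulate: organs, bowel gas, partial
volume effects, beam hardening or metal artifacts, scoliosis or
transitional vertebrae, respiratory variation in body shape along the
scan, or the texture statistics of real tissue. Passing the phantom
study therefore demonstrates that the pipeline's mechanics — geometry,
preprocessing, learning, peak extraction, quantification and the
statistics — are correct and internally consistent; it does not
certify clinical accuracy on patient scans.

## Numerical conventions

* Orientation: everything downstream of loading operates in RAS+ with
  0-based voxel indices; mm positions are `index × spacing` per axis.
* Isotropic resampling: trilinear (`scipy.ndimage.zoom` order 1),
  default target 1 mm (2 mm for phantom work, their native grid).
* Projection: maximum-intensity over the central 50 % sagittal slab
  (mean projection available by configuration).
* Localization error: superior–inferior axis distance in mm (the
  quantity that determines slice selection), plus slice-index error.
* Standard deviations are population (÷N) everywhere: index density
  statistics, Bland–Altman limits of agreement (bias ± 1.96 sd), and
  fold aggregates.
* The under-10-mm percentage uses a strict inequality.
* Dice with both masks empty is defined as 1 (perfect agreement on
  absence); ties in the segmentation argmax go to the lower class
  index; heatmap peaks are filtered by a floor of 0.1 × the global
  maximum and a minimum separation of 2σ, with ties broken toward the
  superior position.
* Slices that are not natively square with side divisible by 16 are
  center-padded with air (−1024 HU) or center-cropped to the 512×512
  default grid.
* An isolated failure to find two heatmap peaks raises a detection
  failure; the pipeline aborts that subject rather than guessing. The
  evaluation harness records such subjects and summarizes the
  remaining ones.

## Open design choices

The publication leaves several details unstated; this package fixes
them as follows: the projection statistic (MIP over a central slab),
per-channel rather than joint normalization of windowed channels, the
isotropic resampling resolution (1 mm), Dice scored on the selected
2D slice (the "volumetric" coefficient degenerates to 2D for
single-slice masks), L1/L3 assignment by anatomical order rather than
peak intensity, 3-class joint softmax for the L1 model, and an
unstratified subject-level k-fold split. Training hyperparameters
(loss, optimizer, learning rate, epochs) are likewise unspecified in
the source and are exposed as configuration.

## Known limitations

* The numpy engine is single-threaded and eager; it is sized for the
  phantom study and small clinical models, not for full-scale training.
* DICOM support covers axial series with uniform spacing and rescale
  tags; enhanced multi-frame DICOM is not parsed.
* No post-processing (largest-component filtering, hole filling) is
  applied to masks by default, matching the source method's silence on
  the point.
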