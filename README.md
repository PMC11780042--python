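# CompositIA

Automated CT body-composition analysis: locate the L1 and L3 vertebral
levels in a thoraco-abdominal CT volume, segment the two axial slices,
and quantify seven body-composition indices — for radiologists and
imaging researchers who need opportunistic bone-density and
muscle/fat measurements from routine scans without manual slice
selection or contouring.

## Method

The pipeline has three stages:

1. **L1/L3 localization** as heatmap regression. The volume
   (canonicalized to RAS+, isotropic voxels) is reduced to a sagittal
   maximum-intensity projection, windowed with three bone-weighted HU
   ranges ([1000, 2000], [400, 500], [800, 1900]), rescaled to [0, 1]
   and resized to 128 × 256. A MultiResUNet predicts a heatmap trained
   on targets built by Gaussian-filtering (σ = 15 px) unit impulses at
   the true centers; the two most intense peaks are the predicted
   centers, the superior one being L1.
2. **Slice segmentation** with two U-Nets: the L1 slice (window
   [-1024, 500] HU) into trabecular and cortical bone; the L3 slice
   (windows [-1024, 2048], [-190, -30], [40, 100] HU as three
   channels) into skeletal muscle (SMA), visceral fat (VAT) and
   subcutaneous fat (SAT).
3. **Quantification**: from the masks and the original HU slices,

   * L1 trabecular BMD average and standard deviation (HU),
   * L1 trabecular bone area (cm²),
   * L3 SAT area, L3 SMA, L3 VAT area (cm²),
   * L3 SAT density standard deviation (HU),

   with areas = pixel count × pixel area / 100 and population standard
   deviations. Agreement statistics (Pearson r/r², Bland–Altman bias
   and limits of agreement bias ± 1.96 sd, percentage relative error
   |pred − truth|/|truth| × 100) and a subject-level k-fold harness
   (k = 5 by default) implement the evaluation protocol.

Because no deep-learning framework is assumed, the networks run on a
small, fully tested numpy autodiff engine inside the package
(`compositia.nn`); the trainable stages are exposed as sklearn-style
estimators (`HeatmapLocalizer`, `SliceSegmenter`) with `fit`/`predict`.

A seeded phantom generator (`compositia.phantom`) renders synthetic
thoraco-abdominal volumes — vertebral column with cortical shell and
trabecular core, ribbed thoracic levels, subcutaneous fat ring, muscle
wall, visceral fat — with exact ground-truth centers and masks, so the
entire pipeline is trainable and testable without patient data.

## Worked example

Train on 64 phantoms and analyze a held-out one:

```python
from compositia import PipelineConfig, generate_dataset
from compositia.pipeline import fit_pipeline

data = generate_dataset(65, seed=42)
config = PipelineConfig(isotropic_spacing=2.0)  # phantom-native grid
pipe = fit_pipeline(data[:64], config)

vol, ann = data[64]
centers, (l1_mask, l3_mask), report = pipe.run(vol)
print(centers.l1_slice, centers.l3_slice, ann.l1_center[2], ann.l3_center[2])
print({k: round(v, 2) for k, v in report.to_dict().items() if k != "subject_id"})
```

prints:

```
77 45 78 46
{'bmd_avg': 160.2, 'bmd_sd': 34.36, 'l1_trab_area': 5.12,
 'l3_sat_area': 38.2, 'l3_sma': 25.52, 'l3_vat_area': 11.4,
 'l3_sat_density_sd': 22.82}
```

i.e. the predicted L1/L3 slices land within one 2-mm voxel of the
truth (77/45 vs 78/46), trabecular density reads ≈160 HU (the
phantom's generating mean; the sd folds in the 10 HU acquisition
noise), and the areas are the phantom's constructed cross-sections
in cm². Training the three models takes ~15 minutes on one CPU.

The same models are reachable from a shell:

```bash
compositia phantom --n 8 --seed 7 --out data/
compositia train --data data/ --out models/ --set isotropic_spacing=2.0
compositia run --input data/phantom_7_000.nii.gz --models-dir models/ --out report.json
```

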