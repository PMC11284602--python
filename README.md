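# phenoplane

Fiducial-calibrated extraction of plant phenotypic traits from RGB images.

A single square marker of known physical side length (default 4.7 cm) placed
beside coplanar plant parts calibrates image pixels onto a metric plane via
an exact four-point homography. Pluggable detection/segmentation backends
supply class-labelled boxes and binary masks, from which six traits are
measured in physical units:

| trait | meaning | units |
|-------|-----------------------------|-------|
| CD    | crown diameter              | mm    |
| PH    | plant height                | cm    |
| PL    | petiole length              | cm    |
| LA / LL / LW | leaf area / length / width | cm² / cm / cm |
| FlA   | flower area                 | cm²   |
| FrA   | fruit area                  | cm²   |

Alongside the measurement pipeline the package provides:

- **backends** — a detection/segmentation contract with an *oracle* backend
  (returns generator ground truth, isolating the geometry pipeline) and a
  *classical* backend (colour thresholding + connected components). A
  learned detector can be slotted in behind the same contract.
- **synthetic_scenes** — a deterministic scene renderer producing images of
  a projectively posed fiducial plus flat plant-proxy parts, with sub-pixel
  ground-truth boxes, pixel-exact masks, and true trait values; plus
  generators for weight-regression and validation datasets.
- **weight_model** — fruit-area → fresh-weight OLS regression (optional
  log-log form), with JSON persistence.
- **stats** — measured-vs-predicted validation (Pearson r, R², RMSE,
  paired t, detection frequency), deterministic 1-D k-means size
  clustering, and one-way ANOVA + Tukey HSD with compact letter display.
- **io_cli** — readers for two annotation dialects (v1 CSV: single-target,
  unlabelled; v2 JSON: multi-target, labelled), results CSV writer,
  annotation tallies, and the command-line interface.

Measurements are valid only for content coplanar with the marker; the
"distortion correction" is the four-point projective rectification (radial
lens terms are not identifiable from four points and are not modelled).

## CLI

```sh
# render synthetic scenes (PNG + ground-truth JSON + v2 annotation export)
phenoplane generate --out scenes/ --seed 1 --count 3 --trait FrA

# detect the fiducial and export the pixel->cm calibration
phenoplane calibrate scenes/scene_FrA_000.png --out cal.json

# measure a trait (classical backend, or oracle with a ground-truth sidecar)
phenoplane measure scenes/scene_FrA_000.png --trait FrA --backend classical
phenoplane measure scenes/scene_FrA_000.png --trait FrA --backend oracle \
    --ground-truth scenes/scene_FrA_000.gt.json --out results.csv

# fit the fruit-area -> fresh-weight regression from an area,weight CSV
phenoplane fit-weight --input pairs.csv --out model.json

# validation statistics / size clustering
phenoplane validate --input measured_predicted.csv --attempts 70
phenoplane cluster --input values.csv --k 3 --seed 0 --out clustered.csv
```

## Library example

```python
import numpy as np
from phenoplane.synthetic_scenes import trait_scene, render_scene
from phenoplane.backends import OracleBackend
from phenoplane.traits import measure_image

rng = np.random.default_rng(0)
image, ground_truth = render_scene(trait_scene("FrA", rng))
[m] = measure_image(image, "FrA", OracleBackend(ground_truth))
print(m.value, m.units)  # fruit area in cm^2, within 1% of ground truth
```

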