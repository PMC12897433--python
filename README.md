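# shgquant

Quantitative collagen-fibrosis analysis of second-harmonic-generation
(SHG) microscopy images: synthetic phantom generation, sliding-window
intensity statistics, random-forest feature ranking, unsupervised label
validation, a single-sigmoid-neuron fibrosis classifier with stratified
20-fold cross-validation, Hough-transform fiber-orientation analysis, and
per-diet-group reporting.

The statistical core (random forest, K-means, the neuron classifier, the
circular statistics) is implemented from scratch so every convention is
explicit and testable; established libraries handle file formats and the
Hough accumulator. See `docs/methods.md` for the full methods note.

## Worked example

```python
import shgquant as sq

# 1. Generate the default study layout: 4 diet groups (C, A, S, AS) x
#    6 animals x 10 images, prevalences 0.08/0.24/0.40/0.62,
#    fiber angular dispersions 26/24/16/2.8 degrees.
dataset = sq.generate_dataset(seed=0)
print(len(dataset), "images,", dataset.labels.sum(), "fibrotic")

# 2. Image-level features; frac_above is the fraction of pixels above
#    the image's noise threshold (mean/10 for non-negative images).
from shgquant.features import image_feature_table
table = image_feature_table(dataset.images)

# 3. Classify with the sigmoid neuron under stratified 20-fold CV.
report = sq.kfold_cv(table["frac_above"].to_numpy(), dataset.labels,
                     k=20, seed=0)
print(f"F1={report.f1:.3f} sensitivity={report.sensitivity:.3f} "
      f"specificity={report.specificity:.3f}")   # 1.000 across the board

# 4. Train on everything, map predictions back to diet groups.
model = sq.train_neuron(table["frac_above"].to_numpy(), dataset.labels)
_, hard = sq.predict(model, table["frac_above"].to_numpy())
preds = dict(zip(dataset.manifest["image_id"], hard))
for s in sq.group_fiber_percentages(preds, dataset.manifest):
    print(f"{s.group}: {s.mean_pct:.1f} ± {s.sd_pct:.1f}% fibrotic images")

# 5. Fiber orientations of the positive images in one group.
from shgquant.orientation import detect_fiber_directions, analyze_angles
dirs = [detect_fiber_directions(img) for img in dataset.images
        if img.group == "AS" and preds[img.image_id]]
angles = analyze_angles(dirs, seed=0)
print(f"AS angular width: {angles.width:.1f} degrees (circular SD)")
```

## Command line

Each pipeline stage is also a CLI subcommand, and `run-all` chains them:

```bash
shgquant run-all --outdir run1 --seed 0
shgquant simulate --outdir data --seed 0
shgquant features data/manifest.csv --stride 10
shgquant cv image_features.csv data/manifest.csv --k 20
```

`run-all` writes the resolved configuration, the manifest and images, the
window/image feature tables, the importance ranking, cluster assignments,
the CV report, per-image predictions, detected fiber angles, per-group
angular widths, and the final mean ± SD report under `--outdir`.
Configuration is flat YAML (see `shgquant/config.py` for every key);
unknown keys are rejected up front.

## Library layout

| module                 | contents                                        |
|------------------------|-------------------------------------------------|
| `shgquant.synth`       | synthetic phantoms and cohort datasets          |
| `shgquant.imgio`       | TIFF/PNG/text images, manifest CSVs             |
| `shgquant.features`    | noise threshold, 7 window statistics            |
| `shgquant.selection`   | from-scratch random-forest importances          |
| `shgquant.clustering`  | from-scratch K-means, label agreement           |
| `shgquant.classifier`  | sigmoid neuron, Adam, stratified k-fold CV      |
| `shgquant.orientation` | Hough fiber detection, circular statistics      |
| `shgquant.cohort`      | per-group mean ± SD percentage reports          |
| `shgquant.pipeline`    | end-to-end orchestration                        |

Narrative walk-throughs of each stage live in `examples/`.

## Reproducibility

All randomness is seeded: every public entry point takes a seed, and the
pipeline derives per-stage sub-seeds from one global seed, so identical
configurations produce byte-identical outputs. `scripts/acceptance.py`
reproduces the headline classification metrics:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` pins the quantitative claims (perfect CV
classification, prevalence recovery, angular-width ordering, oracle
equivalence of the statistics, closed-form thresholds, and cross-checks
of the from-scratch learners against scikit-learn).
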