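# mscpheno

Segmentation and morphological phenotype classification of mesenchymal stem
cells (MSCs) in phase-contrast micrographs.

Cultured bone-marrow MSCs are heterogeneous: rapidly self-replicating (**RS**)
cells are small and spindle-shaped, while slowly replicating (**SR**) cells are
large, flattened and rhomboid. The mix of the two phenotypes predicts a
culture's expansion and differentiation capacity, but scoring it by eye is slow
and subjective. `mscpheno` automates the readout from routine, label-free
phase-contrast images:

1. **Preprocess** — contrast stretch, unsharp masking, anisotropic
   median-diffusion denoising.
2. **Region detection** — Sobel edges at an Otsu-derived threshold,
   morphological connect/fill, then size, intensity and shape filters that drop
   debris and halo artifacts; the edge sensitivity adapts to cell density
   (area fraction below/above 0.1).
3. **Marker detection** — dual-threshold H-minima transform on a
   reconstruction-flattened image finds one marker per nuclear basin, with
   perimeter-based rules for cluster candidates and centroid-distance pruning.
4. **Segmentation** — regions with one marker pass through; regions with
   several are split by marker-controlled watershed.
5. **Features** — 30 named morphometric and texture features per cell (size,
   shape, first-order intensity, and gray-level co-occurrence matrix (GLCM)
   statistics over 24 offset orientations and three image renditions).
6. **Classification** — per-feature measure selection by univariate AUC,
   correlation pruning, SMOTE class balancing, five classifier families
   compared by stratified 5-fold cross-validation, and a soft-voting ensemble
   of the top two, trained per culture day.
7. **Evaluation** — detection counts split into under-/over-segmentation
   categories (FN1/FN2/FP1/FP2), sensitivity, precision, per-cell DICE, and an
   average phenotype score for observer panels.

The package also ships a seeded synthetic micrograph generator
(`mscpheno.fixtures`) that renders super-ellipse cells with halo rims, ruffled
boundaries and single nuclear pits, together with exact ground-truth label
maps — so the whole pipeline is testable without microscope data.

## Worked example

Everything below is deterministic and runs on one CPU in a few minutes; the
printed numbers are what the current package version produces.

### Segment synthetic micrographs and score against truth

```python
import numpy as np
from mscpheno.fixtures import generate_dataset
from mscpheno.segment import segment_image
from mscpheno.evaluate import (
    DetectionCounts, match_detections, per_cell_dice, sensitivity, precision,
)

for preset in ("day2", "day4"):
    _, data = generate_dataset(preset=preset, n_images=3, seed=7)
    total, dices = DetectionCounts(), []
    for img, truth, _ in data:
        res = segment_image(img)
        total = total + match_detections(res.label_map.labels, truth)
        dices += per_cell_dice(res.label_map.labels, truth)["dice"].tolist()
    print(preset, total, f"S={sensitivity(total):.3f}",
          f"P={precision(total):.3f}", f"DICE={np.mean(dices):.3f}")
```

Output:

```
day2 DetectionCounts(TP=15, FN1=0, FN2=0, FP1=0, FP2=1) S=1.000 P=0.938 DICE=0.933
day4 DetectionCounts(TP=40, FN1=0, FN2=1, FP1=0, FP2=1) S=0.976 P=0.976 DICE=0.894
```

The `day2` preset emulates a sparse early-expansion culture (isolated cells,
one debris artifact per field); `day4` adds touching clusters and tops the
field up to a 0.15 area fraction, which switches the region detector into its
moderate-density branch.

### Train and evaluate the phenotype classifier

```python
import numpy as np, warnings
from mscpheno.fixtures import generate_dataset
from mscpheno.preprocess import preprocess_image
from mscpheno.marker_detect import prepare_marker_image
from mscpheno.features import extract_records, select_best_measure, correlation_filter
from mscpheno.classify import train_day_model, empirical_auc

def day_records(preset, n_images, seed):
    _, data = generate_dataset(preset=preset, n_images=n_images, seed=seed,
                               shape=(448, 448))
    recs = []
    for i, (img, labels, phenos) in enumerate(data):
        pre = preprocess_image(img)
        variants = {"gray": img, "preprocessed": pre,
                    "reconstructed": prepare_marker_image(pre, labels > 0)}
        recs += extract_records(labels, variants, f"{preset}_{i}",
                                phenotypes=phenos)
    return recs

for day, preset in ((2, "day2"), (4, "day4")):
    train = day_records(preset, 10, 100 + day)
    test = day_records(preset, 5, 200 + day)
    sel = correlation_filter(select_best_measure(train), train)
    Xtr = np.array([sel.vector(r) for r in train])
    ytr = np.array([r.phenotype == "SR" for r in train], int)
    Xte = np.array([sel.vector(r) for r in test])
    yte = np.array([r.phenotype == "SR" for r in test], int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_day_model(Xtr, ytr, day=day)
    auc = empirical_auc(model.ensemble.predict_proba(Xte), yte)
    print(f"day {day}: {len(sel.retained)} features retained, "
          f"ensemble={model.top_families}, held-out AUC={auc:.3f}")
```

Output:

```
day 2: 12 features retained, ensemble=('LSVM', 'RSVM'), held-out AUC=1.000
day 4: 19 features retained, ensemble=('LSVM', 'RSVM'), held-out AUC=1.000
```

The perfect held-out AUC reflects the synthetic classes: RS cells are drawn
with elongation 2.5–4.0 and SR cells with 1.15–1.8, several pooled standard
deviations apart, so any competent classifier should separate them.

### Command line

```bash
mscpheno --seed 1 simulate --preset day2 --n-images 3 --out data/
mscpheno segment --input data/day2_000.png --output out/
mscpheno evaluate --pred out/ --truth data/ --output report.json
```

`extract-features`, `train` and `classify` subcommands cover the rest of the
pipeline; `mscpheno --help` lists options, and every stage parameter can be
overridden with `--config pipeline.yaml`.

## Reproducing results

- **Test suite** (unit, property-based and end-to-end tests; all randomness is
  seeded):

  ```bash
  python -m pytest -q tests/
  ```

- **Reference metric arithmetic** — recomputes the detection sensitivity and
  precision values from their published count tables and writes them as JSON:

  ```bash
  python scripts/acceptance.py --seed 1 --out results.json
  ```

- The worked examples above are plain scripts: re-running them with the same
  seeds reproduces the printed numbers exactly.

See `docs/methods.md` for the models behind each stage, every tunable
parameter with units and defaults, what the synthetic generator does and does
not emulate, and known limitations.
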