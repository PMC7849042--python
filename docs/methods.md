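# Methods

This note documents the models behind each pipeline stage, the tunable
parameters (units, defaults, rationale), the numerical conventions, and what
the synthetic fixture generator does and does not emulate. Defaults live in
`mscpheno.config`; every value below can be overridden from a YAML file passed
to the CLI or to `load_config`.

Conventions: images are `float64` arrays on the intensity scale [0, 1];
lengths are in pixels unless stated otherwise; the default optical scale is
1.56 px/µm (10× phase contrast, 1280×1024 px sensor). Labels use RS = 0
(rapidly self-replicating, spindle) and SR = 1 (slowly replicating, rhomboid).

## Preprocessing (`mscpheno.preprocess`)

| parameter | default | units | rationale |
|---|---|---|---|
| `contrast_saturation` | 0.01 | fraction/tail | linear stretch between the 1st and 99th percentile; robust to hot pixels |
| `unsharp_radius` | 2.0 | px (Gaussian σ) | matches the 2–3 px halo transition being sharpened |
| `unsharp_amount` | 0.8 | — | boosts edges without ringing the halo into saturation |
| `diffusion_iterations` | 5 | — | enough for texture smoothing; more rounds blur cell–substrate edges |
| `diffusion_kappa` | 0.1 | intensity | conductance scale; gradients ≫ κ (cell borders) are preserved |
| `diffusion_dt` | 0.15 | — | ≤ 0.25 for 4-neighbour stability |

Grayscale conversion uses Rec. 601 luma weights. The anisotropic diffusion is
Perona–Malik with exponential conductance, followed each iteration by a 3×3
median filter, which suppresses impulse noise the diffusion would otherwise
sharpen. A constant image is a fixed point of the whole chain.

## Region detection (`mscpheno.region_detect`)

Sobel gradient magnitude is thresholded at `edge_sensitivity` × the Otsu
threshold of the gradient image; edges are dilated (`se_dilate`, disk radius
2), closed (`se_close`, 3) and hole-filled into candidate objects. The field's
area fraction (AF) then selects a branch at `af_threshold` = 0.1:

- **low density** (AF < 0.1): `edge_sensitivity` = 1.0, one filtering pass;
- **moderate density** (AF ≥ 0.1): edges are recomputed at sensitivity 0.5
  (touching cells weaken the gradient at shared borders) and the object
  filter runs twice.

The object filter removes components by size (absolute floor
`size_abs_min` = 100 px², plus the adaptive rule area ≥ mean − `k_size`·SD with
`k_size` = 2), by interior intensity (components whose interior lacks both
bright and dark extremes — quantiles 0.98/0.02 of the field — are
substrate-toned debris), and by shape (`circularity_max` = `ellipticity_max` =
0.70: adherent MSCs have ruffled, elongated outlines with circularity well
below that of round debris and bubbles). Survivors are opened (`se_open` = 2),
eroded (`se_erode` = 5) and border-clipped. The erosion radius is larger than
the dilation because the initial mask traces the *outer* halo boundary, ~2–3 px
outside the true cell body; eroding by dilation + halo offset returns the
candidate region to body scale, which both improves per-cell DICE and detaches
background pockets trapped between touching cells.

## Marker detection (`mscpheno.marker_detect`)

The preprocessed image is smoothed (Gaussian σ = 1, median radius 1),
contrast-equalized (CLAHE, clip 0.01, 8×8 tiles), and flattened outside the
candidate regions by morphological reconstruction by erosion, so only minima
inside cells survive. Markers are extended minima (H-minima transform):
regional minima of the reconstruction of `img + h` over `img`.

Two depths are used: `h_threshold_A` = 0.30 finds deep nuclear basins,
`h_threshold_B` = 0.12 shallow ones. Per region: A-markers win if present and
the region perimeter is < `cluster_perimeter_min` = 400 px; B-markers are the
fallback; large-perimeter regions (cluster candidates) take the union. Markers
closer than `min_centroid_distance` = 15 px (~10 µm, below the minimum
internuclear distance of adherent MSCs) are merged by keeping the larger, and
markers under `min_marker_area` = 150 px² (~62 µm², below any MSC nuclear
basin) are discarded. The depth thresholds and the area floor were tuned on
the synthetic fixtures: genuine nuclear-basin markers there measure several
hundred px² while spurious minima from boundary ruffles stay below ~70 px².

## Segmentation (`mscpheno.segment`)

Regions are triaged by marker count: zero markers → dropped (no nuclear
evidence), one → accepted as a single cell, two or more → marker-controlled
watershed on the marker image restricted to the region, with watershed lines,
so k markers always yield k cells tiling the region. Each output label carries
a provenance tag (`single` / `from_cluster`).

## Features (`mscpheno.features`)

30 named features per cell: 6 size (µm-scaled area, perimeter, width, height,
major/minor axis), 6 shape (circularity, ellipticity, elongation, solidity,
extent, compactness), 9 first-order intensity and 9 GLCM statistics. Intensity
and texture features are measured on three image renditions — raw grayscale,
preprocessed, and reconstruction-flattened — giving 3 raw measures per
first-order feature and 24 × 3 = 72 per GLCM feature (24 offsets: angles in
15° steps at pixel distance 1; an 8-angle × 3-distance scheme is available via
`glcm_scheme`). The GLCM is symmetric, mask-restricted, and quantized to
`glcm_levels` = 32 gray levels over the masked intensity range (32 levels keep
the 5×5-px-scale co-occurrence counts dense enough to be stable for the
smallest cells).

Per feature, the single best raw measure is chosen by folded univariate
Mann–Whitney AUC (max(AUC, 1−AUC), so inverted separations count equally);
features are then greedily pruned so no retained pair exceeds
`correlation_max` = 0.8 absolute Pearson correlation, keeping the
higher-AUC member.

## Classification (`mscpheno.classify`)

Five families: linear SVM, RBF SVM (both C = 1, probabilities via sigmoid
calibration), LDA (lsqr solver with automatic shrinkage, safe under singular
within-class covariance), k-NN (k = 5), logistic regression (C = 1). Features
are standardized with training statistics only; SMOTE (k = 5) balances the
minority class inside each training fold. Families are ranked by mean
stratified 5-fold cross-validated AUC (seed 17); the top two are fused by
soft voting (mean SR-probability) and refit on all training cells of that
culture day. The decision threshold minimizes
(1 − sensitivity)² + (1 − specificity)² over out-of-fold ensemble scores, ties
resolving to the lower (more sensitive) threshold. Uncertainty on AUC is a
stratified bootstrap percentile interval (2000 replicates).

Day-specific models exist because MSC morphology distributions drift as a
culture expands; pooling days would mix the regimes.

## Evaluation (`mscpheno.evaluate`)

Predicted and truth cells are matched greedily by descending overlap,
one-to-one, requiring intersection > 50 % of the truth cell's area. Errors are
split by whether the cell sits alone or in a cluster (truth cells sharing a
connected component of the candidate-region mask, or of the truth foreground
when no region mask is supplied): FN1/FP1 for isolated cells, FN2/FP2 within
clusters. Sensitivity = TP/(TP+FN1+FN2), precision = TP/(TP+FP1+FP2), both NaN
on empty denominators. Per-cell agreement is the Sørensen–Dice coefficient;
unmatched truth cells score 0. For observer panels, the average phenotype
score (mean of binary RS=0/SR=1 votes) maps to confidence categories at
0.15/0.40/0.60/0.85.

## Synthetic fixtures (`mscpheno.fixtures`)

The generator renders what the pipeline *keys on*, not phase optics:

- cells are smoothed super-ellipses (exponent 2.2) with a sinusoidally
  ruffled boundary; the wobble amplitude/lobe ranges are set so rendered
  circularity lands near 0.4, typical of adherent MSCs and safely below the
  0.70 artifact cutoff;
- intensity ordering bright halo rim (background + 0.18–0.38) > substrate
  (0.5) > cell body (0.40) with one Gaussian nuclear pit (depth 0.22–0.30),
  so marker counts are exact by construction;
- RS cells: elongation 2.5–4.0, strong halo; SR cells: elongation 1.15–1.8,
  larger minor axis, weaker halo, more ruffling;
- debris artifacts (near-circular blobs, thin fibers) with uniform,
  substrate-toned interiors that the region filter should reject;
- background: low-frequency shading (±0.01) plus Gaussian noise (`noise_sd`).

Difficulty is tunable (noise level, inter-cell `gap`, per-phenotype elongation
ranges); presets `day2` (sparse singles) and `day4` (clusters,
`density_target` = 0.15) emulate early and mid-log expansion. All randomness
derives from a single seed via `numpy.random.SeedSequence`; the same seed
reproduces images byte-for-byte.

**Not emulated:** phase-contrast shade-off and halo asymmetry, partial cell
overlap in z, mitotic rounding, debris touching cells, uneven illumination
beyond the gentle shading term, and sensor artifacts. Fixture results
therefore bound what the pipeline can do on clean input; they do not predict
performance on real micrographs.

## Numerical choices

- All intensities are processed as `float64` in [0, 1]; 8-/16-bit files are
  scaled on load and quantized only on save.
- Otsu thresholds are computed on the gradient magnitude, not the intensity
  histogram, making edge detection invariant to background level.
- The H-minima transform is implemented as reconstruction by erosion of
  `img + h` over `img` followed by regional-minima extraction
  (8-connectivity), the standard exact formulation.
- Empirical AUC is the Mann–Whitney statistic with 0.5 credit for ties —
  exact, not trapezoidal.
- SMOTE synthesizes points on segments between a minority sample and one of
  its k minority neighbours; originals are never perturbed.
- Seeds are threaded explicitly everywhere (`numpy.random.default_rng`,
  scikit-learn `random_state`); no global RNG state is used.

## Limitations

- Thresholds (H-minima depths, marker area floor, shape cutoffs, structuring
  element radii) were tuned on the synthetic fixtures; real micrographs from a
  different magnification or camera will need retuning via the YAML config.
- The region detector assumes a bright halo; apodized or low-NA phase images
  with weak halos will under-detect.
- One nuclear basin per cell is assumed; binucleate cells are split.
- The classifier is trained per culture day and does not transfer across
  days or donors without retraining.
- Reported fixture metrics (e.g. held-out AUC 1.000 on elongation-separated
  synthetic classes) measure internal consistency, not clinical performance.
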