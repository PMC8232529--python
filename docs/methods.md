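# Methods

## Problem and approach

`segtemplate` studies a transfer-learning protocol for 3D organ
segmentation: a "template" network is trained on a large dataset whose
annotations are rough, clinically generated contours, and is then used as
the weight initializer when training on small datasets with clean,
research-grade annotations.  The package implements the full protocol —
preprocessing, augmentation, a 3D U-Net with soft Dice loss, grouped
cross-validation, template refinement, dataset ablation — and evaluates it
on synthetic multi-domain phantoms, because the clinical imaging data such
a study runs on cannot be redistributed.  Everything is exercised at desk
scale on one CPU; the synthetic experiments probe the *properties* of the
protocol (transfer ordering, data-size monotonicity, metric correctness),
not the headline accuracy of any clinical model.

## Synthetic phantoms (`phantomgen`)

Each domain is a `DomainSpec`: grid and voxel spacing, organ size and
shape irregularity, organ/background intensities, a linear contrast
gradient along y (coil falloff), additive Gaussian noise, a multiplicative
bias field, and an annotation-roughness amplitude.

* **Organ geometry.** A centred ellipsoid whose radius is modulated by a
  random linear combination of real spherical harmonics of degree ≤ 4,
  scaled so the RMS radial perturbation equals `shape_irregularity` —
  smooth, lobed, organ-like shapes.  The `distractor` task instead
  produces an off-centre main lobe with two attached satellite lobes and
  (in the shipped preset) inverted contrast; it plays the role of an
  unrelated out-of-domain segmentation task.  Masks are reduced to their
  largest 6-connected component and must contain ≥ 10 voxels.
* **Bias field.** The exponential of a random order-3 polynomial in
  normalized coordinates, rescaled so the field lies in
  `[1−s, 1+s]` with unit spatial mean — the low-frequency multiplicative
  model that N4-style correction assumes.
* **Noise** is additive Gaussian (not Rician).  At the SNRs used here the
  difference is immaterial, and the magnitude-clip at zero is applied
  after noise addition; this is a deliberate simplification.
* **Rough annotations.** The clean mask's signed Euclidean distance map
  (in mm) is thresholded at a smooth random displacement field whose RMS
  amplitude is `annotation_roughness_mm`.  The field is strongly smoothed
  in-plane (σ = 6 mm) and only lightly across slices (σ = 1 slice),
  mimicking slice-wise manual contouring with inter-slice jitter.  No
  published quantification of clinical-contour error exists for this
  protocol, so the roughness presets are the package's own choice: 2 mm on
  the full-size primary preset (~14 mm organ radius), giving
  truth-vs-clinical Dice ≈ 0.88, which we consider a plausible severity
  for routine clinical markup.
* **Determinism.**  Every generator is a pure function of (parameters,
  seed); per-case seeds are `blake2b(master_seed, domain, index) mod 2^31`,
  so datasets are reproducible and order-independent.

Shipped presets (`data/domains.yaml`): `primaryA` (large domain, rough
labels, bias 0.3, contrast gradient), `challengeB` (clean labels,
anisotropic 0.6×0.6×1.5 mm voxels), `challengeC` (clean labels, low
contrast), `oodD` (distractor task).

## Preprocessing (`preprocess`)

Fixed order: bias correction → isotropic resampling → IQR normalization →
central crop/pad.  Masks pass only through the geometric steps.

* **Bias correction** delegates to N4 (SimpleITK), with the field
  estimated on a 2× shrunken copy and divided out at full resolution.  The
  contract is behavioral, not bit-exact: on phantoms with a simulated
  bias of strength ≥ 0.2 the within-organ coefficient of variation must
  drop to ≤ 60 % of its uncorrected value.
* **Resampling** to 1 mm isotropic by default; output size per axis is
  `round(extent_mm / target)`; images linear, masks nearest-neighbour.
* **IQR normalization**: `v' = (v − Q1) / (Q3 − Q1)` with quartiles from
  the central in-plane 128×128 column (all slices; the window shrinks to
  the grid when smaller), then clipped to `[−2, +6]` — two IQRs below the
  first quartile, five above the third.  The affine form makes the clip
  bounds land on clean constants and is invariant to positive affine
  intensity changes.  Quantiles use linear interpolation between order
  statistics.  Whether clipping is applied in raw or normalized units is
  indistinguishable under this form.
* **Crop/pad** to 128×128×136 (configurable).  Odd remainders put the
  extra voxel on the high-index side; images pad with −2 (the normalized
  minimum), masks with 0.

## Augmentation (`augment`)

Per epoch, each case yields exactly one augmented sample.  Transforms, in
fixed order: elastic deformation, rotation, y-mirroring, then an in-plane
central crop.  The elastic field is Gaussian-smoothed white noise
(σ = 8 mm) scaled to an RMS displacement of 10 mm (both configurable; the
original augmentation package's parameters are not published, so these
defaults are ours).  Rotation draws an axial-plane angle from
U[−π/8, π/8] and a through-plane tilt about x from U[−π/4, π/4] — the
latter is our reading of rotation "along the axis" as distinct from the
axial-plane rotation.  Mirroring probability is 0.5.  Elastic and rotation
are composed into a single coordinate map so image (linear) and mask
(nearest-neighbour) are each resampled exactly once.  Out-of-bounds voxels
fill with −2 (image) and 0 (mask).  Per-sample seeds derive from
(master seed, epoch, case id); each transform draws from its own derived
stream, so disabling one does not shift the others.

## Model (`segmodel`, `nn`)

A 3D U-Net: four encoder levels, three decoder levels, two
(3×3×3 conv → group norm → ReLU) stages per level, 2×2×2 max pooling,
3×3×3 stride-2 transposed convolutions, skip concatenation, 1×1×1 head
with two-class softmax.  Feature maps double per level from
`base_features`.  Group normalization uses 8 groups (shrunk to the channel
count when below 8); the figure-level mention of batch normalization in
the source architecture diagram is superseded by the text's group
normalization, which we follow.  Exact per-level feature counts of the
original figure are not recoverable from text, so the doubling ladder is
the package default.

The loss is soft Dice on foreground probabilities,
`L = 1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1e−5 guarding empty targets.
Optimization is Adam at batch size 1 (whole volumes).

Because no deep-learning framework is part of the dependency set, the
network is implemented directly in numpy: im2col convolutions backed by
BLAS matmuls, analytic backward passes for every layer, and an Adam
optimizer.  All backward passes are validated against central finite
differences (≤ 1e−6 relative error in float64), which is the strongest
correctness evidence a hand-written engine can offer.

## Training protocols (`trainer`)

* **Folds** are patient-grouped by default: all studies of a patient share
  a fold (the study data has ~1.5 studies per patient and grouping
  prevents leakage; an ungrouped flag exists).  Groups are shuffled
  deterministically and dealt cyclically, so fold sizes differ by at most
  one group.
* **Ablation subsets** are nested: one permutation per seed, prefixes
  taken per fraction (`round(fraction·n)`, minimum 1).  Nesting reduces
  the variance of between-fraction comparisons.
* **Refinement** is cross-validation with every fold's model warm-started
  from the template checkpoint; `epochs=0` evaluates the raw template (the
  "before refining" condition) and provably leaves weights untouched.
* **Evaluation reference.** Training always targets the (possibly rough)
  clinical mask; metrics are computed against the clean truth mask, which
  is the analogue of evaluating against research-grade contours.

### Desk-scale conditions

Study-scale settings (128×128×136 inputs, Adam 1e−5, 100–150 epochs,
five folds) remain the config defaults, but the experiments this package
actually runs use a desk preset chosen to complete on one CPU:
24×24×16 voxel phantoms, `base_features=4`, Adam 3e−3 (batch-1 training
at these sizes makes 1e−5 impractically slow), 16-case primary domain
(12 patients), 12-case challenge domain split 6 train / 6 held-out,
8-case distractor domain; 24 template epochs, 16 fine-tune epochs,
ablation fractions {5 %, 25 %, 100 %}; augmentation off in the suite runs
(it is exercised and tested separately; leaving it off makes each suite
run fully deterministic given its seed).  The desk preset scales
`annotation_roughness_mm` to 1 mm so the contour error relative to the
organ radius matches the full-size preset.  The overfit check uses the
spec-level desk network (base 8, 32³ input, 150 epochs).

## Evaluation (`evalmetrics`)

* **Soft Dice** `2Σpr/(Σp+Σr)`; 1.0 when both masks are empty.  Reported
  Dice uses soft probabilities (binarized evaluation is flag-selectable).
* **Average Hausdorff distance**: halved sum of the two directed mean
  nearest-neighbour distances between all foreground voxel centres
  (reference vs 0.5-thresholded prediction), Euclidean in mm; all
  foreground voxels are used, not only boundary voxels.  Empty masks give
  a *missing* AHD (and Dice 0 for empty predictions); missing counts are
  reported rather than fabricating infinite distances.
* **Subvolume split**: the reference mask's foreground slices split
  25 % / 50 % / 25 % into apex / midgland / base along the slice axis
  (apex end set by the volume's axis convention); quarter blocks round
  half away from zero, midgland takes the remainder, so the blocks always
  partition the slices.  Regional Dice is computed on each slab; overall
  Dice on the full uncropped grid.
* **Aggregation** pools per-image metrics across all folds (not
  fold-means-of-means); SD is the n−1 sample estimate.
* **Paired one-tailed t-test** on per-case differences, alternative
  mean(a−b) > 0, α = 0.001; zero-variance differences yield a flagged
  degenerate result instead of a p-value.

## What passing tests do and do not show

The phantoms reproduce the *statistical structure* the protocol depends
on — domain shifts in contrast/noise/anisotropy, smooth multiplicative
bias, spatially correlated label noise, repeat studies per patient — but
not anatomy, partial-volume effects, Rician noise, motion artifacts, or
the failure modes of real clinical contours (e.g. systematic base/apex
truncation).  A passing suite therefore validates the pipeline's
implementation and the direction of its effects (transfer helps; more
template data helps; in-domain templates beat out-of-domain ones), not
clinical-grade accuracy numbers.

## Numerical choices and limitations

* Dice ε = 1e−5; quantiles by linear interpolation; crop/pad remainders to
  the high-index side; max-pool ties break to the first element;
  group-norm ε = 1e−5.
* Checkpoints store spec, seed, weights and history in a single `.npz`.
* The engine is single-threaded CPU code; study-scale grids (128³×136)
  are supported but slow — the desk presets are the intended operating
  point.
* The 5-seed majority criteria for transfer ordering and ablation
  monotonicity are stochastic by design; individual seeds can and do
  violate strict monotonicity (e.g. a 25 % template occasionally scoring
  below a 5 % one on 6 evaluation cases).
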