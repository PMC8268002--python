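# Methods

`peristas` re-creates, as tested software, an intra- plus perinodular CT
radiomics analysis for predicting spread through air spaces (STAS) in lung
adenocarcinoma. STAS is a histologic invasion pattern — tumor cell clusters
in alveolar spaces beyond the main tumor edge — so the working hypothesis
is that the *perinodular* lung, not only the nodule itself, carries the
predictive signal. The package implements the full chain (VOI geometry,
feature extraction, imbalance-aware modeling, ROC diagnostics) and, because
no patient data ship with it, a phantom generator that plants exactly the
kind of perinodular signal the hypothesis describes.

## VOI geometry

Eight volumes of interest are built per case from a tumor (core) mask and a
lung mask sharing the image geometry:

- **VOI_core** — the tumor mask itself.
- **VOI_2mm … VOI_20mm** — *cumulative* perinodular shells: all lung voxels
  within d mm of the tumor surface, minus the core, for
  d ∈ {2, 4, 6, 8, 10, 20}. Cumulative (surface→d), not annular;
  annular rings are available as a utility (`annular_ring`).
- **VOI_tumor–lung** — the interface band: dilation by 3 mm intersected
  with the lung, minus the 3 mm erosion of the core (3 mm inside + 3 mm
  outside the contour).

Distances are realized by thresholding an exact Euclidean distance
transform with per-axis physical spacing (`scipy.ndimage.
distance_transform_edt(sampling=spacing)`), measured voxel-center to
voxel-center; voxels at exactly d are included. This gives millimeter
accuracy on anisotropic grids, where iterated structuring elements do not.
Every shell is clipped to the lung mask, so VOIs of pleurally attached
nodules never contain extrapulmonary tissue. Multiple connected components
in a core mask are treated as one region. Tests verify the morphology
against a brute-force nearest-neighbor distance oracle, exactly, for
isotropic and anisotropic spacing.

## Feature extraction (851 per VOI, 6,808 per case)

Per VOI: 14 3D shape descriptors, plus a 93-feature intensity/texture
block computed on the original image and on each of the 8 bands of a
single-level 3D discrete wavelet transform:

    93 = 18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM
    851 = 14 + 9 x 93,   6,808 = 8 x 851

The family counts are forced by reconciling the two totals: they only
close if the NGTDM family (5 features) is included alongside the four
matrix families usually named, so it is.

Numerical conventions (all configurable where meaningful):

- **Discretization**: fixed bin width 25 HU, minimum-anchored
  (`floor((x − min)/w) + 1`), no resampling — reconstructions are assumed
  ~1 mm already. Min-anchoring makes every discretized feature invariant
  to global intensity shifts (tested).
- **GLCM**: distance 1, the 13 unique 3D directions, symmetric matrices,
  features computed per direction and averaged (not merged). Degenerate
  single-level regions use limit conventions (0·log 0 = 0, correlation and
  MCC = 1), never NaN.
- **GLRLM**: runs per direction via run-length encoding of in-mask voxels
  ordered along each line; features direction-averaged.
- **GLSZM**: 26-connected zones. **GLDM**: dependence = 1 + number of
  equal-level 26-neighbors (α = 0, distance 1). **NGTDM**: 26-neighborhood
  mean differences.
- **Wavelet**: Coiflet-1, one level, periodization padding (orthogonal, so
  coefficient energy is conserved); each of the 2³ low/high combinations is
  reconstructed to the original grid so masks apply unchanged. The eight
  band reconstructions sum to the input (tested to 1e−10).
- **Shape**: marching cubes on the lightly Gaussian-smoothed indicator
  (σ = 0.7 voxels, falling back to the binary surface for structures the
  smoothing would drop below the iso-level); this removes the stair-step
  area bias, so a digital 10 mm ball scores sphericity ≈ 0.99. Axis
  lengths come from PCA of physical voxel centers, maximum diameters from
  the convex hull. Shape is computed for hollow shell VOIs too, where mesh
  area/volume remain well defined.

All five matrix families are verified against exhaustive enumeration
oracles (pair walking, run walking, BFS flood fill, neighbor counting) on
random ≤ 4×4×4 grids with masked voxels, and the direction-averaged
features against 90° rotation invariance. Exact agreement with any
particular external package's values is *not* a goal: extraction settings
(bin width, aggregation, padding) are implementation-defined; counts,
invariants and oracle agreement are the contract.

A VOI with < 2 voxels (an empty shell when a tumor fills its lung region)
contributes a NaN sentinel block; such cases are excluded downstream with
a logged reason.

## Modeling chain

Per model: z-score standardization → Pearson-correlation deduplication
(|ρ| > 0.99 drops the later feature in scan order; absolute value guards
anti-correlated duplicates) → SMOTE class balancing → recursive feature
elimination with AdaBoost importances → AdaBoost (decision-tree weak
learners, SAMME).

- **Split**: stratified 80/20 with per-class floor rounding
  (56/160 → 172 train / 44 test).
- **SMOTE**: synthetic minority case = x + u·(x_nn − x), u ~ U(0,1), x_nn
  among k = 5 nearest minority neighbors (k reduced with a warning for
  tiny minorities). Applied to training data only — inside each CV
  training fold, never to test folds; oversampling before the fold split
  would leak synthetic copies of validation cases into training and is
  rejected by design.
- **RFE**: drops the lowest-importance half of the features per iteration
  until the target count (20 for the full-scale eight-VOI configuration).
- **Cross-validation**: stratified 5-fold; the full preprocessing chain is
  refit inside every training fold; out-of-fold probabilities can be
  averaged over repeated iterations (default 5 at full configuration; the
  simulation studies use 1). Leakage is audited by a null calibration:
  pure-noise features must give out-of-fold AUC ≈ 0.5 (tested).
- **Grid search** (optional): picks (n_estimators, max_depth) maximizing
  mean validation-fold AUC; ties break toward fewer estimators, then
  shallower trees. RFE is nested inside each grid evaluation.
- **Nine models**: the eight single-VOI models and the combined eight-VOI
  model, each runnable per feature group (first-order+shape, texture,
  wavelet, all), sharing one case split.
- **Serialization**: model bundles round-trip through JSON (tree node
  arrays embedded); the reloaded model reproduces probabilities
  bit-identically (tested).

## Evaluation

Continuous scores: Mann–Whitney AUC with half-credit ties; operating point
by maximum Youden J (ties toward higher sensitivity, then lower threshold);
sensitivity/specificity/accuracy/PPV/NPV at that cutoff; 95% CI by
stratified percentile bootstrap (default 1,000 resamples); correlated ROC
comparison by the DeLong placement-value test (two-sided). Binary signs
from 2×2 counts use AUC = (sens + spec)/2 — the area under the
single-operating-point ROC polygon — which is verified to agree exactly
with the Mann–Whitney AUC of the corresponding 0/1 predictor on all small
contingency tables. Zero-denominator rates are reported as undefined
(NaN), not 0.

## Phantom generator

Each case is a Hounsfield-unit volume (default 80³ at 1×1×1 mm; anisotropic
spacing supported) containing a soft-tissue body (+40 HU), two ellipsoidal
lungs (−800 HU, Gaussian noise SD 25 HU), and one ellipsoidal nodule:

- diameter ~ N(19.7, 6.2²) mm truncated to [10, 50] and to what the grid
  holds with a 20 mm margin (the emulated cohort's size distribution);
- consolidation-to-tumor ratio ~ N(0.7, 0.3²) clipped to [0, 1]: the solid
  core (0–60 HU) occupies the CTR fraction of the depth from the surface,
  the rest is ground-glass (−600 to −300 HU);
- 30% of nodules seat against the pleural boundary (shells then clip).

The STAS-positive signal is strictly perinodular, within 10 mm of the
surface, scaled by `peritumoral_effect` (default 1): a Gaussian-blurred
interface rim (σ = 1 mm · effect over the 3 mm rim), added smoothed
heterogeneity (60 HU · effect), and Poisson(4 · effect) hyperdense 1–3 mm
satellite micro-clusters. Nodule size, CTR and intensities are drawn from
the same distributions for both classes, so the core-only model is
handicapped *by construction* — the designed property the simulation
studies test. With effect 0 the classes are exchangeable everywhere
outside the core (verified by a type-I-error check over 100 replicates).

Randomness flows through one seeded generator; per-case seeds are hashed
from (master seed, case index) via `numpy.random.SeedSequence`, so any
case is reproducible in isolation.

What the phantoms do **not** emulate: airway/vessel trees, lobar anatomy,
scanner/dose/reconstruction effects, histology-dependent morphology, and
any real quantitative CT appearance of STAS (no such description exists;
the planted form is a modeling choice). Passing cohort tests therefore
demonstrates that the *pipeline* detects a perinodular signal when one
exists and invents none when it does not — not that real STAS is
detectable at any particular AUC.

## Problem sizes and study configurations

The package's own study configurations, chosen to keep a full run on one
CPU tractable:

- Cohort simulation studies: 216 cases (56 STAS+ / 160 STAS−), 10 master
  seeds per condition, per-VOI *first-order* features (18 × 8 = 144
  columns) — the planted signal is an intensity/heterogeneity signal, so
  the first-order block is the matched detector; texture/wavelet blocks
  are exercised on single cases and small grids instead. Models use
  5-fold CV, one iteration, 30 estimators, RFE to 10 features, no grid.
- The null condition's per-model AUC is summarized as the median over the
  10 seeds (a single 216-case out-of-fold AUC has SD ≈ 0.045 at chance).
- Full 6,808-column extraction is demonstrated per case (~10 s on a
  64³ case) rather than per cohort.

## Known limitations

- Feature values are implementation-defined where the field has no single
  convention (bin width, wavelet basis, GLCM aggregation); only counts,
  invariants, limits, and oracle agreement are contractual.
- Binary-sign AUC = (sens+spec)/2 is a single-operating-point convention;
  it is not comparable to a continuous model's AUC beyond the polygon
  interpretation.
- SMOTE with few minority cases (< k+1) degrades to fewer neighbors.
- The workflow's NIfTI outputs are gzip-compressed; determinism is
  asserted on the results tables (CSV/JSON), which are byte-stable.
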