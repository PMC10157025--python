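# Methods

This note documents the models and procedures implemented in `wmius`, the
assumptions behind them, and the choices made where the design was open.

## Problem setting

White matter injury (WMI) in preterm infants appears on coronal cranial
B-mode ultrasound as altered periventricular echogenicity and texture.
The package implements a complete diagnostic strategy around that signal:
a radiomics system (texture features from a delineated white-matter ROI,
sparse feature selection, cost-sensitive SVM), a segmentation network to
replace manual delineation, and a multi-task network that segments and
classifies jointly. Because no clinical cohort of this kind is publicly
deposited, a synthetic-cohort generator reproduces the *statistical
structure* of such a study (about 160 subjects, 20% subject-level
prevalence, 3–6 frames per subject, speckle-textured frames with one ROI
each) so that every stage is exercised end to end.

## Synthetic cohort generator

A frame is constructed in display (gray-level) units:

    B(x) = M(x) + sigma * u(x),  clipped to [0, 255] and quantized to uint8

- `M` is the anatomy field: a base brightness (105) plus a smooth Gaussian
  random surface (amplitude 12, correlation length 25 px), plus an
  echogenicity bump over the ROI. The bump is the mask smoothed with a
  Gaussian (sigma 2 px) and normalized so its in-ROI mean is exactly 1;
  its amplitude is `roi_base_echo` (12) for every subject — white matter
  is mildly echogenic in all infants, otherwise the delineation task would
  be ill-posed — plus `effect_echo` (default 25) for WMI subjects.
  Calibrating in display units makes `effect_echo` directly interpretable:
  the expected between-class within-ROI mean shift in final gray levels.
- `u` is standardized log-compressed speckle: the log-magnitude of a
  correlated complex Gaussian field (a Rayleigh-like envelope, correlation
  length 1.5 px), standardized per field; `sigma = noise_sigma` (18 gray
  levels). For WMI frames the in-ROI speckle comes from an envelope whose
  correlation length is multiplied by `effect_texture` (1.6), so texture
  features — not only first-order ones — carry class signal.
- The ROI is a connected elliptical band (outer ellipse minus a concentric
  inner one at 45% of the axes), placed off-center, jittered per subject
  and per frame, covering 5–20% of pixels. Geometry outside that range
  raises a configuration error.
- Prevalence is applied as round-half-up on `n_subjects x prevalence`
  (158 x 0.203 → 32); frames per subject are uniform on [3, 6].

With `effect_echo = 0` and `effect_texture = 1` the two classes are
generated by identical processes, which is the exchangeability null the
tests rely on. What the generator does **not** emulate: fan-beam geometry,
attenuation/shadowing, anatomical context outside the ROI, inter-observer
delineation variability, and multi-plane acquisition. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under a controlled image model, not clinical performance.

## Feature system (350 features)

Each (image, mask) pair yields 70 features per image mode across 5 modes:
the original frame and the four subbands (A/H/V/D) of a single-level
**undecimated** (stationary) wavelet transform. Undecimated subbands keep
the source grid, so the same mask indexes all five modes with no
resampling convention; the default family is Haar (configurable via
PyWavelets), with symmetric (mirror) boundary handling.

Per mode: 16 first-order features on raw in-mask intensities (Entropy and
Uniformity on the discretized histogram), 23 GLCM, 13 GLRLM, 13 GLSZM and
5 NGTDM features on intensities uniformly discretized into `Ng = 32`
levels between the ROI minimum and maximum. `Ng` is a common radiomics
default; it keeps matrices small and estimable at ROI sizes of a few
thousand pixels. Conventions:

- GLCM: distance 1, four angles, symmetric accumulation, pairs with either
  pixel outside the mask discarded, features averaged at feature level
  over angles. The Maximal Correlation Coefficient is the square root of
  the second-largest eigenvalue magnitude of the Q-matrix over occupied
  levels.
- GLRLM: maximal in-mask runs along four directions; out-of-mask pixels
  break runs; feature-level direction averaging.
- GLSZM: zones are 8-connected equal-level components; a single
  orientation-free matrix.
- NGTDM: radius-1 Chebyshev neighborhoods, out-of-mask neighbors excluded
  from the neighbor mean; pixels with no valid neighbor are skipped.
- Degenerate denominators use an explicit `eps = 1e-6` convention instead
  of NaN: Correlation is 1 on a constant ROI, Coarseness saturates at
  `1/eps`, IMC1 is 0 when both marginal entropies vanish, skewness and
  kurtosis are 0 at zero variance.
- The 23-feature GLCM battery retains two legacy alias pairs
  (Homogeneity1 = InverseDifference, Homogeneity2 =
  InverseDifferenceMoment) as distinct named columns, because the
  23-name battery this package reproduces enumerates all four names.

Every matrix family is verified against an independently written
brute-force counting oracle (explicit pixel walking, flood fill, loop
formulas) on hundreds of random small masked grids at 1e-9 tolerance.

## Feature selection (sparse representation + bootstrap)

Standardized feature columns are treated as dictionary atoms; the class
label vector coded ±1 is represented as a sparse linear combination of
them via L1-penalized regression. The penalty is chosen once per call
from a regularization path so that roughly 15% of coefficients are active
per fit. On each of `B = 100` bootstrap resamples (rows resampled with
replacement, stratified by class to protect the ~20% minority), the
absolute coefficients are recorded; the importance index is their mean
over bootstraps, and features are ranked by it with ties broken by index.
A greedy orthogonal-matching-pursuit solver is available behind
`SparsityConfig(solver="omp")`. Rows are canonicalized by
column-order-free sort keys before resampling, making the importance
invariant to row order and equivariant to column permutations.

Retention keeps the top fraction (default 20%: 70 of 350) or a fixed
top-k (e.g. the 52-feature operating point). Both entry points exist
because the reported clinical operating point (52 features) differs from
the 20% rule (70) without an explanation linking them; the feature-count sweep
(`auc_vs_k_sweep`) reports AUC as a function of k so the operating point
can be found empirically.

## Classification

A soft-margin SVC (RBF default, linear by config) with class weights
inverse to class frequency (`class_weight="balanced"`), standardization
fitted on training rows only. Hyperparameters are selected by stratified
inner cross-validation maximizing AUC over cost {0.1, 1, 10, 100} and,
for RBF, gamma = scale-heuristic x {0.1, 1, 10}. Scores are continuous
decision-function values; the operating threshold for the confusion-based
indexes is frozen at the Youden point of the *training* scores, so test
rows never influence it. Evaluation is per frame; subject-level
aggregation (mean score per subject) is left to the caller.

## Evaluation battery

AUC is the rank-based (Mann–Whitney) statistic with half-credit ties.
ACC/SENS/SPEC are reported in percent from the confusion counts, which
are always included so every derived number is auditable. LR+ =
SENS/(1−SPEC) and LR− = (1−SENS)/SPEC; at SPEC = 100% the LR+ is reported
capped at 1/eps (1e6) with a flag rather than infinity. Segmentation is
summarized per image by Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B| and
pixel accuracy, with empty-vs-empty defined as a perfect match; the
identity Dice = 2·IoU/(1+IoU) holds per image and is asserted in tests.
Cross-validation partitions subjects (never frames) into label-stratified
folds.

Two quirks of the reported clinical tables are surfaced rather than
reproduced: the testing-cohort ACC (87.88) is inconsistent with its own SENS/SPEC and
cohort sizes (the implied value is ~92.5%), and one multi-task row prints
Dice < IoU, which is impossible per image. The package always reports
counts alongside percentages so such inconsistencies cannot hide.

## Networks

Both models are compact convolutional networks implemented directly on
NumPy with a minimal reverse-mode tape (im2col 3x3/1x1 convolutions,
ReLU, 2x2 max pooling, nearest upsampling, skip concatenation, dense
heads, Adam). This keeps training fully deterministic given a seed and
dependency-light; gradient correctness is checked numerically in the
test suite.

- Segmentation net: a two-stage encoder (base width 8, doubling per
  stage), bottleneck, and a symmetric decoder with skip connections;
  1x1-convolution mask head; loss = binary cross-entropy + soft Dice;
  Adam lr 1e-3.
- Multi-task net: the same encoder and mask decoder, plus a classification
  head (global average pooling → 16-unit hidden layer → logit) and a box
  head (same shape, 4 sigmoid outputs regressing the reference mask's
  tight bounding box in normalized coordinates, smooth-L1 with beta 0.1).
  Joint loss weights mask:label:box = 1:1:0.5; Adam lr 2e-4. At inference
  the emitted box is clamped to contain the support of the binarized
  predicted mask — containment is part of the output contract.

Training follows the imbalanced-cohort scheme: each epoch contains every
majority-class frame once plus minority frames drawn from a fixed shuffled
rotation, continued across epochs, until the epoch reaches a 1:1 ratio
(cyclic fairness: usage counts never differ by more than one); frames are
augmented by joint random translation (±10% of size, integer pixels),
rotation (±15°, bilinear image / nearest mask) and horizontal flip
(p = 0.5). The full-scale clinical profile (100 epochs, batch 4, Adam 1e-3 / 2e-4)
is available as `reference_profile()`; the desk profile used throughout the
tests and the acceptance script runs 64x64 frames, base width 8, 6–20
epochs, which is sized for a few CPU-minutes per training while still
reaching held-out Dice ≥ 0.7 (segmentation, high-contrast cohort) and
AUC ≥ 0.8 (multi-task classification). Desk-scale problem sizes used in
the acceptance script: 45 subjects at 96x96 for the radiomics chain, 40
subjects at 64x64 for the networks.

## Pipeline

One YAML config drives three modes: `radiomics-golden` (features from
reference masks), `radiomics-auto` (test-cohort features from
segmentation-net predictions, with a whole-image fallback if a prediction
is empty), and `mtl-direct` (multi-task net output evaluated directly).
A single global seed fans out to per-stage seeds by fixed offsets, so
stages are independently reproducible and two runs of the same config are
byte-identical. A mask-degradation utility (random boundary erosion or
dilation of configurable radius) provides the controlled analog of
automatic-segmentation error; on synthetic cohorts, increasing
degradation never improves the radiomics-auto AUC on average, mirroring
the golden-vs-automatic comparison.

## Known limitations

- The image model is additive-in-log-domain with planted effects; it does
  not simulate ultrasound physics, and absolute performance numbers on it
  say nothing about clinical data.
- First-order features are computed on raw intensities (discretization
  only for Entropy/Uniformity); a fully discretized variant would differ.
- The sparse-representation selector is a linear representation of the
  label vector; nonlinear feature-label relationships are only found if
  they induce linear correlation after standardization.
- The multi-task model is a compact three-head network, not a detector
  stack with region proposals; it honors the same output contract (mask,
  label, box) at a scale appropriate for single-ROI frames.
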