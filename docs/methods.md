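# Methods

## The classification problem

Each observation unit is one oocyte undergoing Piezo-ICSI, recorded as a
short microscope movie (8-bit frames, nominally 960 × 540 at 30 fps) up to
the frame where the puncture outcome is confirmed. The binary outcome is
whether the oolemma ruptured during membrane extension. The pipeline asks
whether cytoplasm texture in the frames *before* puncturing predicts that
outcome, and evaluates the answer over a grid of three design knobs: the
number of sampled pre-puncture frames (1–5), the retained PCA
dimensionality (1–11), and the SVM kernel (linear, RBF, polynomial,
sigmoid) — 220 evaluation cells in all.

## Frame sampling

Given a reference ("first confirmed") frame index `r`, `n` sampling frames
are taken at indices `r − k·6` for `k = n..1`, i.e. strictly before the
reference frame at a fixed stride of 6. The stride is the smallest integer
interval "more than five frames"; with 30 fps material, the widest pattern
(5 frames) spans 30 frames ≈ 1 s before puncture, which matches the
protocol's intent. Both the stride and whether the reference frame itself
could be included are configurable (`interval`, plus direct index access),
since the original protocol wording admits more than one reading; the
default is the strict-before, stride-6 rule. A sequence must satisfy
`r ≥ 6·n` or sampling raises an error naming the minimum required length.

## ROI and grayscale

The analysis window is 380 × 370 px — the stated size that encloses a whole
oocyte — placed by configuration; the default centers it in the frame, since
the original per-oocyte placement is unspecified. Crops are half-open,
0-based, (row, column) order, and pure windowing (no resampling). RGB input
converts via ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B, rounded), the
standard choice for video-derived stills; the conversion the original study
used is not stated. For frames smaller than the default window (reduced
synthetic cohorts), the centered ROI shrinks to the frame.

## LBP features

For every interior pixel, the 8 neighbors of its 3 × 3 neighborhood are
compared to the center; bit `i` is 1 iff `p_i − p_c ≥ 0`, and the code is
`Σ bit_i · 2^i`. Conventions pinned here:

- **Tie direction.** `≥ 0` means equal neighbors count as 1, so a constant
  patch codes to 255. The opposite ("prose") convention — bit 1 iff the
  neighbor is not greater — is available via `LBPConfig(threshold="prose")`
  for sensitivity analysis; on integer images it is the bit-complement,
  hence a pure histogram permutation with identical downstream geometry.
- **Bit order.** Neighbors are enumerated clockwise from the top-left
  offset (−1, −1); any fixed enumeration permutes bins without changing
  separability, so the choice is frozen purely for reproducibility.
- **Border.** The 1-pixel border is excluded rather than padded; padding
  would invent image content. An H × W crop yields (H−2)(W−2) codes.
- **Normalization.** Default is density (bins sum to 1), making features
  invariant to ROI size; counts mode is retained for raw-histogram work.

Rotation-invariant/uniform LBP variants and multi-radius sampling are out
of scope; the method is defined on the square 3 × 3, N = 8 case.

## PCA

Classical covariance PCA: mean `m`, population covariance
`S = (1/N) Σ (x_n − m)(x_n − m)ᵀ` (divisor `N`, deliberately, matching the
covariance definition the pipeline standardizes on), eigenpairs of `S` by
`numpy.linalg.eigh`, sorted by descending eigenvalue with a stable sort.
Eigenvector signs are arbitrary, so each vector is flipped to make its
largest-magnitude entry positive — outputs are then bit-reproducible.
Projection of `x` onto `d` components is `u_jᵀ(x − m)`, `j = 1..d`.
`d` beyond the covariance rank is allowed; trailing components carry ≈ 0
variance and no signal. Within cross-validation the basis is fitted on the
training folds only (default `pca_scope="train"`); fitting on all data
would leak the held-out oocyte into the transform and is available only as
an explicit comparison flag.

## SVM

Soft-margin SVM with the discriminant
`f(x) = sgn(Σ_i w_i K(x, x_i) + b)` over support vectors, and kernels

- linear: `x₁ᵀx₂`
- RBF: `exp(−γ‖x₁ − x₂‖²)`
- polynomial: `(x₁ᵀx₂ + c)^d`
- sigmoid: `tanh(b·x₁ᵀx₂ + c)`

Kernel evaluation and prediction are implemented in this package; the dual
quadratic program is solved by libsvm via scikit-learn's `SVC` with a
precomputed Gram matrix — a replaceable component behind the train/predict
contract, cross-checked in tests against an independent projected-gradient
dual solver. Hyperparameters are not part of the method definition, so the
defaults follow mainstream SVM practice: `C = 1`; `γ` and the sigmoid slope
default to `1/(n_features · var(X))`; polynomial degree 3 with `c = 1`;
sigmoid `c = 0`. All are exposed in configuration. `sgn(0) = +1`
(ruptured): borderline cases err toward the clinically cautious call.
Ruptured is the positive class throughout. No class weighting is applied
by default (all samples are used as-is); the sigmoid kernel is indefinite
and can behave erratically, which is faithful to its definition.

### Feature units

Density LBP histograms have Euclidean norms of order 10⁻², and so do their
PCA projections. The polynomial and sigmoid kernels add an O(1) constant to
an O(10⁻⁴) data term, and `C = 1` then acts as extreme regularization —
every fold collapses to the training majority class. The pipeline therefore
divides projected features (train and test alike) by a single scalar fitted
on the training fold: the root-mean-square row norm. This is a units choice,
not a geometric transformation — directions, ratios and the PCA ordering are
untouched, and the held-out oocyte never influences the scalar. It is on by
default (`feature_scaling="norm"`) and can be disabled.

## Cross-validation and metrics

Leave-one-oocyte-out: each fold holds out *all* sampled frames of one
oocyte; features of the remaining oocytes fit the PCA basis and train the
SVM; each held-out frame is predicted individually. Predictions are counted
per frame, not per oocyte, so a cell evaluated at `n` frames on `m` oocytes
accumulates a confusion matrix with `m·n` entries. With `n = 1` the scheme
is ordinary leave-one-out. Accuracy, sensitivity and specificity are
`100·(TP+TN)/total`, `100·TP/(TP+FN)` and `100·TN/(TN+FP)`, displayed to
two decimals (half-up); a zero denominator yields a NaN marker in reports
rather than an exception. The association test is the Pearson chi-square on
the 2 × 2 (true × predicted) table, 1 df, without Yates correction (a
continuity-corrected variant is a flag); a zero margin returns an
undefined-test marker. The test is computed per cell. A degenerate training
fold containing a single class (possible only with one oocyte of a class)
degrades to a constant classifier predicting that class, so the minimal
two-oocyte cross-validation is well defined.

The grid sweep shares work across cells without changing any number:
feature sets for fewer sampling frames are suffixes of the widest set, and
the per-fold PCA eigenbasis does not depend on how many components are
later retained, so it is fitted once per (fold, frame-count) and sliced.

## Aggregate tables

Two report tables aggregate per-cell accuracy: by sampling frames
(averaging over dimensionality) and by dimensionality (averaging over
sampling frames), per kernel. The SD is the sample form (divisor n−1) and
the "amount of change" column is the difference between consecutive rows'
*unrounded* means, rounded half-up to two decimals only for display. Both
conventions are pinned by the published polynomial-kernel rows: the
11 per-cell accuracies at 2 sampling frames give 82.45 ± 8.31, and the
frames 2→3 change is 0.08 (differencing rounded means would give 0.09;
population SD would give 7.93). Aggregation over an incomplete grid raises
an error listing the missing cells.

## Synthetic cohort generator

The generator emulates what the analysis assumes, with the oocyte as the
independent unit:

- **Geometry.** A circular cytoplasm disc (radius ≈ 0.28–0.32 of the
  shorter frame side) with a darker annulus (zona pellucida, width
  ≈ 0.022 of the shorter side, ≥ 2 px) on a near-uniform bright
  background (190), cytoplasm base intensity 128, ring 90 — plausible
  inverted-microscope contrast. Geometry that does not fit the frame is a
  configuration error.
- **Texture.** Band-limited Gaussian speckle: white noise smoothed by a
  Gaussian of σ = `texture_scale` pixels, standardized, scaled by
  `texture_contrast` × 60 gray levels. LBP histograms respond monotonically
  to both parameters (correlation length through code statistics, contrast
  through quantization tie rates), giving a clean effect-size dial.
- **Classes.** Nonruptured oocytes draw `texture_scale ~ N(3.0, 0.2²)` px
  and `texture_contrast ~ N(0.35, 0.03²)`; ruptured means shift by
  `+0.5·class_effect` px and `+0.05·class_effect` respectively. Defaults:
  38 ruptured + 55 nonruptured, 960 × 540 frames, 31 frames per movie
  (long enough for the widest sampling pattern), reference frame = last,
  `class_effect = 1.0` as a moderate, detectable-but-imperfect condition;
  `class_effect = 2.0` is used as the "large effect" condition in tests
  and the acceptance script, `0` makes the classes identically distributed.
- **Temporal correlation.** All frames of a movie share one base speckle
  field; each frame adds a per-frame jitter field normalized to unit peak
  and weighted 0.05, so two frames differ by at most
  `2 × 0.05 × 60 × texture_contrast` gray levels (before 8-bit rounding) —
  a hard, testable bound. Zero contrast yields a constant interior.
- **Reproducibility.** Per-oocyte seeds derive deterministically from
  `(master_seed, oocyte_index)`; every frame is re-renderable in isolation
  from its spec, and identical configurations produce byte-identical
  rasters.

What the generator does **not** model: the pipette and holding pipette, the
rupture event itself, chromatic content (frames are grayscale), uneven
illumination, focus drift, and real biological texture statistics — the
parameter ranges are engineering choices, not estimates of clinical data.
Passing tests on synthetic cohorts therefore demonstrate that the pipeline
recovers a texture-statistics signal under its own assumptions, not that
the clinical accuracy is reproduced; the original cohort is not public, so
its headline numbers are outside what any reimplementation can verify.

## Problem sizes and null calibration

Test and verification runs use reduced cohorts (typically 20–60 oocytes at
320 × 240 or smaller, with the centered ROI shrunk to the frame) — the
statistics of interest do not require full-size rasters — while the
large-effect recovery check runs at the full default geometry (93 oocytes,
960 × 540). On a zero-effect cohort, the best of 220 grid cells is a
maximum statistic over correlated cells, and frames of one oocyte are
correlated; its chance band is therefore the Bonferroni-adjusted binomial
quantile at the oocyte level (n = 60), not a per-cell frame-count band.
A single designated cell is additionally checked against its unadjusted
95% binomial band. The balanced null cohort (30 + 30) keeps the
majority-class collapse point at 50% rather than at the 55/93 base rate.

## Known limitations

- Real clinical hyperparameters (C, γ, degree, coef) are unknown; defaults
  are conventional, and conclusions about kernel ranking on synthetic data
  need not transfer to clinical movies.
- The LOOCV majority-flip pathology biases chance-level accuracy below 50%
  in small balanced cohorts; per-cell accuracies under the null are not
  exactly binomial.
- Video container decoding, automatic puncture-frame detection and
  automatic oocyte localization for ROI placement are out of scope; frames,
  labels and reference indices are inputs.
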