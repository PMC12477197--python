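# Methods

## Problem and scope

An IVF laboratory question: can the extended-culture outcome of a Day 3
embryo — morphologically good blastocyst (A), non-good blastocyst (B), or
clinically non-useful embryo (C) — be predicted non-invasively from Raman
spectra of the spent culture medium the embryo grew in? The package
implements the full analysis chain as a reusable library: spectral
preprocessing, per-peak group statistics, chemometric embeddings, a
12-family classifier comparison with class balancing, stacking of the
best models, and mode-vote aggregation of replicate spectra into one
decision per sample.

The original spectral cohort (172 samples, 30-40 replicate spectra each)
is not publicly deposited, so a synthetic-spectrum generator is a
first-class component: it produces cohorts with the statistical structure
the analysis assumes, and every pipeline property is established against
that stated world.

## Synthetic cohort

One sample = one embryo's medium droplet; groups A/B/C of 58/25/89
samples; each sample yields a uniform-random 30-40 replicate spectra on
the 300-3400 cm⁻¹ grid at 1 cm⁻¹ (3101 points).

A spectrum is

```
y(nu) = sum_k a_k * exp(-(nu - p_k)^2 / (2 s_k^2)) + b(nu) + eps(nu) + spikes
```

* **Peaks.** 18 Gaussian core peaks at 506, 620, 642, 662, 750, 850, 898,
  938, 1000, 1030, 1120, 1202, 1332, 1446, 1605, 1654, 2874 and
  2926 cm⁻¹ with widths σ 5-12 cm⁻¹ (narrow in the crowded fingerprint,
  broader in the CH-stretch region, chosen so all 18 stay resolved strict
  local maxima on the default grid). Each peak carries one of the ten
  group-intensity patterns (e.g. A>B>C at 750 and 938, A≈B≈C at 1120 and
  1654). Adjacent groups in a pattern differ by a relative gap
  d = 0.2 × `separability` (default 1.0 → 20%); "≈" groups get *exactly
  equal* means, so any downstream significance on such a pair is a type-I
  error by construction. Single-pair patterns (B>A at 506, C>B at 2874)
  put the pair endpoints at ±d/2 and the third group exactly midway.
* **Amplitudes.** Hierarchical lognormal: a per-(sample, peak) factor
  exp(N(0, `sample_cv`=0.15)) shared by all replicates of the sample,
  times a per-replicate factor exp(N(0, `amplitude_cv`=0.10)). The sample
  random effect makes replicate predictions within a sample positively
  correlated — the regime in which per-sample mode voting is a
  non-trivial operation.
* **Area balance.** Base amplitudes were solved once (minimum relative
  deviation from a hand-picked set under three linear constraints) so the
  three groups have identical total spectral area. Without this, area
  normalization to a fixed total would rescale groups differently and
  manufacture spurious between-group differences at the equal-mean peaks.
  Values are stored rounded to 3 decimals (residual imbalance ~4×10⁻⁵
  relative, far below any detectable group difference).
* **Baseline.** Quadratic drift plus one broad Gaussian hump
  (center 1400 cm⁻¹, σ 500 cm⁻¹), coefficients jittered 10% per spectrum —
  enough structure to make asymmetric-least-squares correction do real work.
* **Noise and spikes.** Additive Gaussian noise (sd 0.02 against peak
  amplitudes 0.15-1.1); cosmic-ray spikes as Poisson(0.3)-count,
  1-2-point-wide positive excursions of ~8× the local signal. The
  generator draws amplitudes, baseline, noise and spikes from separate
  seeded substreams, so switching spikes off reproduces the identical
  underlying spectra (the spike-free truth used by the despiking tests).

What the generator does **not** emulate: instrument wavelength error,
detector etaloning, fluorescence photobleaching kinetics, site-to-site
heterogeneity on the dried drop, or any real biochemistry (no peak
assignments). A green test therefore establishes that the pipeline is
correct and calibrated on data with the assumed statistical structure —
not that the published real-data performance is reproduced.

## Preprocessing

Order is fixed and order matters (regression-tested): QC → despike →
truncate/resample → AsLS baseline → Savitzky-Golay smoothing → area
normalization.

* **QC.** The exclusion rule is this package's construction (the source
  protocol names only "signal-to-noise" inspection). SNR = (max −
  median of the smoothed, baseline-corrected signal in 600-1800 cm⁻¹) /
  (1.4826 × MAD of the smoothing residual in the 1800-2600 cm⁻¹ silent
  region); default threshold 3. The median subtraction matters: an
  asymmetric baseline hugs the lower envelope, so pure noise otherwise
  carries a positive offset proportional to its own σ and would pass any
  fixed threshold. Every exclusion is logged with a reason.
* **Despiking.** "Filter size 4, dynamic factor 6" interpreted as: flag
  |y − runmed₉(y)| > 6 × max(local, global) robust scale, where local =
  1.4826 × runmed₉|y − runmed₉(y)| and global is the spectrum-wide
  analogue; replace flagged points by the running median. The global
  floor is needed because a 9-point MAD is itself so noisy that ordinary
  noise gets flagged. Limits: on grids much coarser than ~2 cm⁻¹ the
  narrowest real peaks (σ 5 cm⁻¹) span <2 points and become
  indistinguishable from spikes; and at peak-to-noise ratios beyond a few
  hundred a sharp apex can exceed any median-window threshold. Both are
  outside the generator's stated world (1 cm⁻¹ grid, SNR ≈ 50).
* **Resampling.** Linear interpolation onto 300, 301, ..., 3400 cm⁻¹
  inclusive (3101 points); inputs must span the range.
* **AsLS.** Eilers-Boelens iterative asymmetric least squares: minimize
  Σ wᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)², w = p above the baseline and 1−p below,
  reweighted to convergence or 10 iterations; defaults λ=1e5, p=0.01 (the
  canonical values; the protocol states none). The normal equations are
  pentadiagonal and solved with a symmetric banded Cholesky
  (`solveh_banded`), ~0.5 ms per 3101-point iteration; an independent
  dense solve is the test oracle at p=0.5 where the weights are constant.
* **Smoothing.** Savitzky-Golay, order 3. The stated window of 10 is
  even, which the construction disallows; default 11 (nearest odd ≥ 10),
  configurable, with the error message suggesting the odd neighbour.
* **Normalization.** Intensities scaled so their *sum* is exactly 100
  ("total intensity" read as the sum of sampled intensities; on a uniform
  1 cm⁻¹ grid this differs from the trapezoidal integral only at the
  endpoints).

## Peak patterns

Peak intensity = maximum within ±5 cm⁻¹ of the nominal position. Groups
are compared pairwise with the two-sided Mann-Whitney U (spectral
intensities are skewed; Welch's t available), stars at 0.05/0.01/0.001
per pair without multiplicity correction — matching figure-style
annotation — with a Holm-within-peak option for experiments that need
family-wise control across a peak's three pairs.

The classifier maps (mean ordering, significance flags) to one of the
ten reference labels: four full orderings (all pairs significant), three
one-equal-pair configurations, two single-pair directions, and A≈B≈C;
anything else returns `other` rather than being coerced.

Units of analysis: `spectrum` (pooled replicates, default — reproduces
figure-style star magnitudes but inherits pseudo-replication from the
sample random effect) or `sample` (per-sample means, independent
observations). Pattern-recovery experiments use `sample`. On the seeded
default cohort 16/18 encoded labels are recovered; the two single-pair
peaks (506, 2874) place the third group midway between the pair, so at
cohort-level power all three pairs reach significance and those peaks
classify as their full orderings (A<C<B, B<A<C) — an expected property
of the encoding, not a pipeline defect.

## Embeddings

* **t-SNE**: library implementation, PCA init, seeded.
* **"LaDA"**: the source describes Latent Dirichlet Allocation as a
  supervised method; LDA-the-topic-model is unsupervised. We fit
  unsupervised LDA topics on pseudo-count spectra (rounded 100× the
  normalized intensities) and fill the "supervised" role by colouring
  with known labels. How the original analysis supervised it cannot be
  determined from the text.
* **OPLS-DA**: from scratch, NIPALS. One-hot class matrix, both X and Y
  centred; `n_orth` orthogonal components (default 1) are estimated and
  removed — for each, the PLS weight is computed, the X-loading's
  component orthogonal to it extracted, and the corresponding variation
  deflated — then predictive PLS components are fitted on the filtered
  matrix (two components for three classes; for two classes the
  embedding is predictive score 1 vs orthogonal score 1). Diagnostics
  R²X (X variance modelled) and R²Y (class variance explained). The
  defining invariance — predictive scores unmoved by an added
  class-orthogonal nuisance direction — is property-tested.

## Classification protocol

* **Split**: per group, floor(0.8 n) samples to training (58/25/89 →
  46+20+71 = 137 train, 35 prediction). All replicate spectra of a sample
  stay on one side; CV folds are likewise sample-level (stricter than the
  source, which does not state it).
* **SMOTE**: written in-package (`imbalanced-learn` not available):
  minority classes are oversampled to the majority count with convex
  combinations of a row and one of its k=5 nearest same-class neighbours;
  originals preserved verbatim. Applied to training spectra only, after
  the sample-level split.
* **Registry** (12 families): MLP = 2-hidden-layer (128, 64) and ANN =
  1-hidden-layer (64) perceptrons with early stopping (the source does
  not distinguish them; this is our convention); GRU = a from-scratch
  numpy single-layer GRU (hidden 32) over 50-point patches of the
  spectrum, trained with Adam and early stopping, gradients verified
  against finite differences (no deep-learning framework is assumed);
  GB/KNN/RF/LSVM/LDA/LR/QDA/NB from scikit-learn (QDA with eigen solver
  + shrinkage — class covariances are rank-deficient when features
  outnumber class spectra); RSVM = RBF SVM trained on a random stratified
  10% subset of candidate support vectors. Traditional families get
  5-fold sample-level CV over deliberately small grids (≤12
  configurations).
* **Metrics**: per-class sensitivity = one-vs-rest recall, specificity =
  one-vs-rest true-negative rate, overall = macro averages, accuracy =
  fraction correct, per-class one-vs-rest ROC-AUC from predicted
  probabilities.
* **Stacking**: top-4 by prediction accuracy (ties by sensitivity, then
  name); base models produce out-of-fold probabilities via sample-level
  5-fold on the training spectra; the meta-learner is multinomial
  logistic regression on the concatenated probabilities (standard
  Wolpert stacking — the source does not name its meta-model); bases are
  refitted on all training data for deployment.
* **Sample decision**: mode of the replicate labels; ties break by mean
  predicted probability among tied labels, then class prevalence, then
  alphabetically (fully deterministic). The fraction-correct histogram
  uses fixed 10% bins and reports the share of samples above 1/2.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` substreams; fixing the seed fixes every
  generated array bit-for-bit.
* Real-data performance tables are *protocol shape only* — the original
  spectra are unavailable, so no test asserts those numbers; properties
  (chance-level calibration on shuffled labels, stacking
  non-degradation within 0.03, mode-vote amplification) are asserted on
  seeded synthetic cohorts instead.
* Model-level tests run on coarse grids (4-8 cm⁻¹, fingerprint region)
  to stay within minutes on one CPU; preprocessing-fidelity tests always
  use the default 1 cm⁻¹ grid.
* Degenerate inputs: zero within-class variance breaks the sklearn
  discriminant solvers (absolute eigenvalue tolerance), so the
  interpolation-regime tests use small nonzero noise; AsLS baseline
  recovery is specified off-peak (the penalty spreads a peak's pull over
  ~λ^(1/4) points, producing a small shoulder undershoot that grows with
  peak area).
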