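# Methods

## Problem setting

A tissue-microarray (TMA) study provides, per patient, 1–4 H&E-stained
1-mm core images (~2500×2500 px at 20×) and patient-level labels for
five binary tasks: tumor grade (low-intermediate vs high), ER status,
Basal-like vs non-Basal-like PAM50 subtype, ductal vs lobular
histology, and ROR-PT risk class (continuous score dichotomized at
64.7). Labels attach to patients, not pixels, so the classifier is a
multiple-instance learner: image regions are scored individually and
the distribution of region scores is aggregated into a patient call.

## Pipeline

### Stain and intensity normalization

RGB → optical density via OD = −log10(I/255). Pixels with total OD ≤
0.15 are treated as glass and carry zero stain concentration. The two
dominant stain directions are estimated per image: the OD cloud of
tissue pixels is projected onto the top-2 eigenplane of its covariance,
and the stain vectors are the directions at the 1st/99th percentile
angles of the projected cloud (robust extremes), ordered
hematoxylin-first by red-channel OD. Per-pixel concentrations are the
non-negative least-squares coefficients on these vectors, rescaled so
their 99th-percentile maxima match a fixed reference profile (vectors
(0.65, 0.70, 0.29) and (0.07, 0.99, 0.11); maxima 1.9705, 1.0308), and
the image is reconstructed in reference colors. The map is idempotent
to within ~1 gray level and sends glass to pure white. A blank image
(no pixel above the OD floor) raises a "no tissue" error rather than
returning a degenerate normalization.

### Tissue mask and tiling

Tissue = total stain concentration > 0.15, with connected components
below 64 px removed. Tiles are enumerated on stride multiples from
(0, 0), fully inside the image, and kept iff mean tissue fraction ≥ 0.5
(computed via a summed-area table). Defaults: 800 px tiles, stride 800
in training and 400 (overlapping) at test time; the training-time
filter uses the same 50 % rule as test time. Regions are addressed by
0-based top-left offset, row-major.

### Feature extraction

Both backends produce a feature grid at 1/8 of pixel resolution and a
region vector as the arithmetic mean of grid cells covered by the
region footprint (pixel offsets divided by 8, floored at the start,
ceiled at the end, so every contributing cell counts).

* `cnn_intermediate`: output of the fourth VGG16 convolutional block
  before max pooling (512 channels, downsampling 8), using ImageNet
  weights via torch/torchvision. Unavailable weights raise an error
  that names the fallback. Note a 2500×2500 input yields a 312×312 grid
  under factor-8 downsampling; smaller published grid sizes correspond
  to cropped inputs.
* `filterbank` (default, self-contained): 30 isotropic response maps on
  the two stain-concentration channels and their sum — Gaussian
  intensities (σ = 1, 2, 4), gradient magnitudes (σ = 1, 2, 4),
  scale-normalized Laplacian-of-Gaussian blob responses (σ = 2, 4, 8),
  and a second-moment map — block-averaged 8×8 and zero-padded to d.
  Isotropic filters make the pooled descriptor rotation-insensitive.

Features are z-scored per dimension with training-set statistics before
any SVM (linear SVMs are scale-sensitive; the statistics travel with
the trained ensemble).

### Instance-level calibrated ensemble

Training patients are split into 5 class-stratified folds *by patient*
(never by region) so no patient's regions appear on both sides of the
fit/calibration boundary. Member k is a linear SVM (liblinear,
squared-hinge, dual=False) fit on folds ≠ k with per-sample weights,
plus an isotonic regression (pooled adjacent violators, clipped to
[0, 1], out-of-range scores clamp to the nearest plateau) fit on fold
k's decision values against the weak region labels. The SVM cost C is
selected once from {0.01, 0.1, 1} by mean weighted calibration-fold
accuracy. The region probability is the mean of the five calibrated
outputs — non-decreasing in each member's score by construction.

Sample weighting: `uniform_class` equalizes total class weights;
`grade_by_class` equalizes the four (grade-bin × class) cells — weight
K/count(cell) with K chosen so the mean weight is 1. ER and Basal-like
tasks default to grade-by-class to reduce grade's leverage on molecular
labels; grade, histology and ROR use uniform-class.

### Quantile-signature aggregation

A bag's region probabilities (pooled over all the patient's cores) are
summarized by the empirical quantile function at 16 equally spaced
levels q_i = i/15 (extremes included, linear interpolation between
order statistics, so value 0 is the minimum and value 15 the maximum).
The alternative midpoint convention (i + 0.5)/16 is available as a
switch. The signature is permutation-invariant and, for interpolated
quantiles, invariant to duplicating the sample only up to O(1/n) knot
shifts — exact invariance would require a step inverse-CDF.

The patient model is a linear SVM on the 16-dim signatures with sigmoid
(Platt) calibration; the sigmoid is a logistic fit on decision values
from 5 held-out folds of the training patients, after which the SVM is
refit on all patients. SVM sample weights carry a fixed total so the
fit depends on the signature distribution rather than the sample count
(duplicating the training set is a no-op). Core-level predictions reuse
the patient-trained model on a single core's signature; a plain
mean-of-region-probabilities score is also provided. Patients or cores
whose regions are all filtered out raise an explicit unscorable error.

### Classification and cut points

Calls are positive iff probability strictly exceeds the task cut: 0.80
(high grade), 0.50 (ER+), 0.60 (Basal-like), 0.20 (high ROR-PT), 0.10
(lobular). `select_cut_point` re-derives a cut by maximizing Youden's J
(or accuracy) over midpoints of adjacent distinct probabilities, ties
resolving to the lowest candidate.

## Concordance statistics

2×2 tables with predictions on rows, reference on columns, index 1 the
positive/sensitivity class. Accuracy, sensitivity, specificity and
percent agreement are reported as integer percentages; Cohen's κ to two
decimals with a 95 % CI from the asymptotic SE
√(p_o(1−p_o)/(n(1−p_e)²)) (the Fleiss–Cohen–Everitt variance is
available behind a flag; the two differ mainly in small strata).
Zero reference margins yield N/A rates; degenerate marginals yield N/A
κ. Chi-square homogeneity uses Pearson's statistic without continuity
correction on raw counts; odds ratios use ad/bc with the Woolf logit CI
and a flagged Haldane +0.5 correction for zero cells.

## Synthetic cohort generator

The generator is the test bed standing in for the restricted-access
cohort, emulating:

* **Marginals** — training-set raw-count frequencies of the source
  cohort: high grade 240/570, ER+ 405/569, Basal-like 92/374; ROR-high
  188/648 and lobular 82/820 from the core-level reference margins
  (patient-level marginals unpublished; survey-weighted percentages out
  of scope because the sampling weights are unpublished).
* **Grade–ER confounding** — a configurable odds ratio (default 6)
  between low-intermediate grade and ER positivity, solved so both
  marginals are preserved; intrinsic subtype is drawn conditional on ER
  (Basal-like predominantly ER−).
* **ROR threshold invariant** — ROR continuous is uniform on [0, 100]
  by default; when a class frequency is configured it is drawn
  piecewise-uniform on the two sides of 64.7 so the threshold identity
  holds exactly.
* **Cores and split** — 1–4 cores per patient, uniform (the source
  states only the range); per-patient random 2/3–1/3 train/test
  partition.
* **Feature bags** — per-region vectors from spherical unit-variance
  Gaussians whose means are separated by `effect_size` (default 3)
  along a fixed task direction; each region flips to the opposite class
  with probability `heterogeneity` (default 0.1), modeling intra-tumor
  heterogeneity. Non-grade tasks additionally receive a
  `grade_effect_size` (default 1) shift along a grade direction chosen
  orthogonal to the task direction, so grade confounding is present and
  the de-confounding effect of grade-by-class weighting is measurable
  against the planted axis. The closed-form Bayes AUC between the two
  instance classes is Φ(effect_size/√2) — 0.983 at the default — which
  bounds every instance-level result.
* **Procedural core images** — a circular tissue disc (radius 0.47 ×
  side) of eosin-pink stroma with hematoxylin-blue nucleus-like blobs
  on near-white glass; blob density and size increase with grade; small
  clear holes mimic fat/lumen. Deterministic per (record, seed).

What the generator does **not** emulate: real nuclear morphology,
stain batch effects, scanner artifacts, spatial correlation between
neighboring regions, or any genuinely hard decision boundary. Passing
tests therefore demonstrate that the pipeline recovers planted signal
under the stated noise model — not that real histology reaches these
accuracies; the published concordance tables are the record of
real-data performance.

## Problem sizes and numerical choices

* Test and acceptance runs use 200 train / 100 test patients,
  feature dimension 64, 8 regions per core — the cohort size, effect
  size 3 and heterogeneity 0.1 define the parameter-recovery study
  condition; d and regions/core are the package's own choice of a
  representative scale.
* Determinism: every stochastic step (cohort, bags, folds, images)
  derives from explicit integer seeds via numpy Generators; liblinear
  runs with fixed random_state and dual=False.
* Degenerate inputs are errors, not silent defaults: empty bags,
  single-class folds or label sets, blank images, zero-expected-count
  chi-square cells, unknown tasks.
* Isotonic ties use average pooling (scikit-learn's PAV); quantiles use
  numpy's "linear" method, which matches the i/15 level convention.

## Known limitations

* The CNN backend needs torch/torchvision with ImageNet weights; the
  default environment exercises the filter-bank path only.
* The asymptotic κ CI reproduces the published overall-row intervals
  but not the small-stratum intervals, whose generating formula is
  unstated in the source tables.
* Core-level evaluation applies the patient-trained signature model to
  single-core signatures; whether the published core-level tables used
  this or plain probability averaging is not documented — both are
  implemented, the signature route is the default.
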