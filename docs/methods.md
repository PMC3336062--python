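# Methods

This document describes every algorithm in `hmfuse`, its parameters, and
all tie-breaking conventions and deliberate deviations. All methods are
implemented from scratch; scikit-learn appears only as an independent
oracle in the test suite.

## Preprocessing (`hmfuse.preprocess`)

### Asymmetric least squares (ALS) baseline

`als_baseline(intensity, lam=1e6, p=1e-3, n_iter=10)` estimates a smooth
baseline `z` by iteratively reweighted penalized least squares: the
objective is `sum_i w_i (x_i - z_i)^2 + lam * sum (Δ² z)^2` with weights
`w_i = p` where `x_i > z_i` (points above the baseline, i.e. peaks, are
nearly ignored) and `w_i = 1 - p` below. Returns `(baseline, corrected)`.
Large `lam` with tiny `p` recovers constant/affine baselines to ~1e-7;
`lam=1e3, p=1e-4` tracks a cubic baseline under peaks to ~0.02 absolute
error on the test signals.

### Parametric time warping (PTW) alignment

`ptw_align(signal, reference, degree=2)` fits a polynomial index warp
`u(i) = a0 + a1*i + a2*i²` by Gauss–Newton on the squared residual between
the warped, linearly interpolated signal and the reference, initialized at
the identity `(0, 1, 0)`. Returns `(coeffs, aligned)`; `coeffs[0]` is the
recovered shift in points. Constant reference or length mismatch is an
error; degree is limited to 2.

### Total-area normalization and autoscaling

`total_area_normalize` divides each spectrum by its summed intensity so
rows sum to exactly 1; non-positive total area is an error naming the
offending sample. `autoscale` mean-centers each column and divides by its
sample standard deviation (ddof=1); zero-variance columns are an error.
`autoscale_fit_tolerant` is the internal variant that leaves zero-variance
columns centered but unscaled (needed inside CV loops where a resampled
fold can be degenerate). Scalers store `mean_`/`sd_` and are always fit on
training rows only.

### Adaptive intelligent (AI) binning

`ai_bin(block, noise_region, min_bin_width, quality_exponent=1.0)`
recursively splits the spectrum: a candidate boundary is accepted where it
maximizes the gain in bin quality, defined from the summed edge-to-maximum
intensity differences of the resulting sub-bins. Recursion stops when no
split improves quality, respecting `min_bin_width` (in ppm). Bins whose
median per-sample maximum stays below three standard deviations of the
signal-free `noise_region` are flagged as noise; `BinTable.signal()` drops
them. Deviation: the classical formulation raises bin quality to a tuned
exponent; here the exponent defaults to 1.0 (no tuning), which already
places the boundary of the documented toy vector
`[0,0,5,9,5,0,0,4,8,4,0,0]` inside its zero valley. Bin values are
trapezoidal integrals over half-open ppm intervals.

### Pipeline

`preprocess_block` applies, per spectrum: ALS correction → PTW alignment to
the block's median spectrum → total-area normalization → AI binning →
noise-bin removal. Autoscaling is deferred to the modeling steps so that
scalers can be fit on training rows only.

## Variable selection (`hmfuse.feature_selection`)

### Linear SVM (SMO)

`train_linear_svm(X, y, C=1.0)` solves the soft-margin dual by sequential
minimal optimization with working-pair selection by maximal KKT violation,
tolerance 1e-10, and bias from the average over free support vectors. The
primal weights obey the identity `w = Σ_{i∈φ} α_i y_i x_i` over support
vectors φ (α > 1e-10) to 1e-8 on every fit; the dual matches a brute-force
QP oracle to 1e-6 on small problems.

### SVM-RFE and LOOCV frequency selection

`rfe_rank` eliminates the variable with the smallest squared primal weight,
refits, and repeats; the returned ranking is best-first. `loocv_select`
runs the ranking inside a leave-one-out loop: for each fold an inner
5-fold stratified CV over the nested subset sizes picks the smallest k
minimizing error; the fold's top-k variables are marked. Variables chosen
at least `median(counts) + 1` times (lower median for even fold counts)
form the selection; an empty result raises `EmptySelectionError`. Results
are deterministic given the seed (used only for the inner CV fold
assignment).

## PLS modeling (`hmfuse.plsda`)

`pls_fit` implements NIPALS PLS1/PLS2 with optional autoscaling of X and y
(`scale=True` used throughout). Requesting more components than the
centered rank raises `RankError`. At full rank PLS predictions equal OLS
on the autoscaled data to 1e-8.

`rmsecv_select_lv` computes the leave-one-out RMSECV curve over component
counts 1..max_a, autoscaling each training fold independently
(tolerant scaler); when a fold's rank is exhausted the last attainable
prediction is carried forward, and the smallest component count wins ties.

`fit_binary_plsda` codes class_a = −1 and class_b = +1, picks the number of
latent variables by RMSECV unless given, and predicts by the sign of the
predicted coded response with ties going to class_b. `validate(X, y)`
records `test_accuracy_`. `fit_pls2da` regresses a one-hot class matrix
(≥3 classes) and predicts by argmax of the predicted columns.

## Mid-level fusion (`hmfuse.fusion`)

`midlevel_fuse` concatenates the selected raw bin values of both blocks —
block A columns first — on the samples present in both blocks (exclusive
samples are dropped with a logged count), records per-variable provenance
(block, bin boundaries, source column), and fits the scaler on the
training rows only. `fuse_and_select` then re-runs LOOCV SVM-RFE on the
fused, scaled training rows of the two contrasted classes.

## Hierarchical Models Fusion (`hmfuse.hmf`)

Validated binary PLS-DA node models are ordered into a decision tree.
Each node contributes one score axis: every sample (regardless of which
classes the node was trained on) is passed through the node's scaler and
projected on its first latent-variable weight vector (Xscore, Yscore,
Zscore, ...). `build_hmf` enforces consecutive steps from 1, one decision
path per class, and a recorded test validation per node.

`hmf_predict` descends the tree: the sign of the node's predicted coded
response routes a sample to the terminal class set or the next node; exact
zeros go to the class-B side. `routing_accuracy` is the fraction of
samples whose terminal path contains their true class. Score-axis pairs
with |Pearson r| > 0.3 are reported as orthogonality warnings.

### Permutation test

`permutation_test_hmf` refits the node classifiers on their fixed variable
subsets (selection is not rerun — a documented choice; rerunning selection
199+ times is computationally prohibitive and the fixed-column null is the
conservative, structure-preserving one) for each permuted label vector and
recomputes the routing statistic on the held-out rows;
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` with `n_perm ≥ 99`.

Labels are permuted **within the training set and within the test set
separately**. Permuting across the fixed train/test boundary changes the
class composition of each set, which makes the null statistics
systematically different from the observed one (a composition-biased
classifier meets a complementarily skewed test set) and produces
non-uniform p-values under the null. The within-set scheme is a proper
group action containing the identity, so under the null the observed
statistic is exchangeable with the null draws and the p-value is exactly
uniform — ties are broken by a seeded infinitesimal jitter. Minimum
attainable p is therefore exactly `1/(n_perm+1)`.

## Duplex splitting and metrics (`hmfuse.model_selection`)

`duplex_split` works per class on autoscaled data: the two mutually
farthest remaining samples (Euclidean) go to the **training** set first,
the next farthest pair to the test set, alternating until the test quota
is reached; leftovers go to training. Conventions: the first pair goes to
training; within a pair the lower index is listed first (membership is
unaffected); the per-class test quota is `max(1, floor(fraction·n + 0.5))`
(round-half-up — a documented deviation from plain `floor(fraction·n)`;
both stay within one sample of the requested share, and the rule was fixed
before any end-to-end evaluation). Classes with fewer than 4 samples are
an error. The split is fully deterministic.

`correct_classification` reports overall and per-class percent correct and
the confusion table; the overall rate equals the class-size-weighted mean
of the per-class rates. `expected_random_accuracy(6)` is 16.7%, printing
as 17% at zero decimals.

`run_experiment` orchestrates the whole pipeline on the synthetic study:
simulate → preprocess both blocks → one Duplex split (25% test) on the
concatenated bins → per-block selection for the three binary contrasts
(C10 vs P10, P10 vs N10, N10 vs N14) → fusion with re-selection → binary
PLS-DA nodes (validated on held-out samples) → three-node HMF with the
path map {step1:A → C10,C14,P14; step2:A → P10; step3:A → N10;
step3:B → N14} → scores, routing, PLS2-DA baseline, optional permutation
test. Artifacts are written as CSV/JSON when an output directory is given.

## Synthetic study generator (`hmfuse.synthetic`)

Six groups (C10, C14, P10, P14, N10, N14), two blocks with partially
shared metabolite libraries, lognormal biological variation (σ = 0.12)
shared per animal across blocks, per-spectrum shift jitter, and known
ground truth (true concentrations, planted contrasts, discriminatory ppm
regions).

The default configuration plants three orthogonal contrast families:

* **peripheral** (P10, N10, N14 vs the rest; P14 reverts to control):
  lactate up, tyrosine down;
* **neurological** (N10 and N14 only): glutamine, myo-inositol, valine,
  acetate, with opposite glutamine direction in P10;
* **severity** (N10 vs N14): creatine, citrate, alanine moving in opposite
  directions between the two diseased time points.

Metabolites listed in `exchange_metabolites` carry an anti-correlated
between-block exchange term (σ = 0.40): per animal and metabolite a draw
ξ multiplies the concentration by exp(+ξ) in block A and exp(−ξ) in
block B. A single block therefore sees each affected contrast through
heavy noise, while the fused blocks cancel it — making mid-level fusion
genuinely better than either block alone, not an artifact of more
variables. Glucose is given a small biological σ (0.04) so total-area
normalization has a quiet reference; formate and glutamate factors in P10
balance the total spectral area so normalization does not leak the class
into every bin. All draws derive from a single seed; identical
configurations produce byte-identical studies.

### Known honest failure at the fixed evaluation seed

The generator design was frozen using design seeds 100–107 only. At the
separate evaluation seed 7, the fused 1-LV P10-vs-N10 model is perfect
while both single-block analogs are imperfect (the fusion motif holds),
but the HMF misroutes 1 of 24 held-out samples (0.958 vs the required
exact 1.0) and the Xscore/Zscore correlation is 0.39 (limit 0.3). The
pre-registered per-seed estimates on the design seeds showed exact routing
in 3/8 and all correlations < 0.3 in 5/8 seeds, so this outcome is within
the expected variability. Per the pre-registered commitment, no parameter
was adjusted after observing the seed-7 result; the two corresponding
acceptance tests fail and are reported as such.
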