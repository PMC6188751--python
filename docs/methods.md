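# Methods

This note records the models, conventions and numerical choices behind
`emphymil`, in particular everywhere a choice had to be frozen that the
problem statement leaves open.

## Multiple-instance model and the quantile relaxation

Bags are subjects; instances are texture descriptors of random 41³ patches
inside the lung mask (50 per subject). Weak labels come from two channels:
`copd` (+1 iff GOLD class A–D) and `dlco` (+1 iff DLCO < 60 % predicted).

The bag/instance link is the upper nearest-rank quantile
`quantile_agg(values, q)`: the k-th largest value with
`k = ceil((1-q)·n)` clamped to `[1, n]`. Consequences worth spelling out:

- `q = 1` is the max (classical witness rule); a positive bag needs one
  positive instance.
- `q = 0.5` is the median; half the instances must be positive.
- Lower q is *stricter*: `q = 0.25` requires 75 % positive instances. The
  grid {0.25, 0.5, 0.75, 0.9, 1} therefore spans "three quarters of the
  lung must look emphysematous" to "one patch suffices".
- No interpolation: the operator acts on ±1 labels during training, where
  interpolated values are meaningless. One convention had to be frozen;
  nearest-rank keeps `quantile_agg(·, 1) ≡ max` exactly.

### miSVM-Q

Optimization is the standard iterative label-imputation heuristic rather
than exact mixed-integer search (which is exponential in bag size):
initialize instance labels at their bag labels; train a kernel SVM
(sklearn `SVC`, precomputed kernel); re-impute — instances of negative bags
stay −1, in each positive bag labels follow the decision-value sign but the
top `m = max(1, ceil((1-q)·n_i))` instances by decision value are forced
positive so the bag's quantile constraint holds; stop when the imputation
is stable or after 20 rounds (ties on equal decision values break by stable
instance index). On non-convergence the best iterate by training bag
accuracy is returned with `converged=False`. The heuristic is validated by
its q=1 agreement with an independently coded max-based miSVM and, on tiny
separable bag sets, with exhaustive search over all feasible instance-label
assignments; no bitwise fidelity to any other implementation is claimed.

### MILES-Q

Bags are embedded against all training instances by the quantile kernel
similarity; an L1-penalized linear SVM (sklearn `LinearSVC`, squared hinge,
`dual=False`) realizes the 1-norm classifier and its nonzero weights define
the prototypes. The instance-scoring rule is not dictated by the bag-level
model; the rule here credits an instance with a prototype's weighted
similarity exactly when the instance sits in the top-k set that determines
the bag's quantile aggregate for that prototype (ties at the k-th value all
credited), plus the intercept. Bags of identical instances then reproduce
the bag posterior exactly, and the rule reduces to the classical MILES
contribution rule at q=1.

### Shared conventions

- Features are z-scored with training-fold statistics before any kernel
  evaluation; the RBF bandwidth grid {8…20} is interpreted on that scale
  (raw feature scales differ by orders of magnitude, and a fixed bandwidth
  grid is only meaningful after standardization — an assumption, flagged).
- Polynomial kernels are inhomogeneous: `(x·z + 1)^p`, p ∈ {1, 2}.
- Posteriors come from a Platt-style sigmoid fitted on training decision
  values (logistic regression on the 1-D decision value, C=100); if the
  fitted slope is negative (degenerate calibration sets) a unit-slope
  sigmoid centred on the mean decision value is used so the posterior map
  is always monotone nondecreasing.
- Class-balanced SVM weighting is off (nothing suggests otherwise).

## Co-occurrence features

- Quantization: HU clamped to (−1024, 0) and binned into 32 equal-width
  levels; values at the upper clamp map to the top level. 32 levels keep
  41³-patch GLCMs well populated; the level count is not prescribed
  anywhere, so it is fixed here.
- 13 directions (one per non-antiparallel 26-neighbour offset) × distances
  {1..5} voxels; symmetric accumulation (matrix plus transpose), normalized
  to sum 1.
- 12 statistics in frozen order: energy, entropy (log base 2; empty cells
  contribute 0), correlation (0 when a marginal variance vanishes),
  contrast, homogeneity (Σ p/(1+|i−j|)), variance (Σ (i−μx)² p), sum mean
  (½ Σ (i+j) p), inverse difference moment (Σ p/(1+(i−j)²)), inertia,
  cluster shade and cluster tendency (third/second central moments of i+j),
  max probability. **Contrast and inertia coincide** (both Σ (i−j)² p in
  the reference formulations); both slots are kept deliberately rather than
  deduplicating, so the descriptor stays 780-dimensional.
- Ordering: direction-major, then distance ascending, then statistic.

## Gaussian filter bank

- Scales are physical (mm) and converted to voxels via the spacing; kernels
  truncate at 4σ; σ below 0.3 voxels raises (undersampled kernel).
- Smoothing is normalized convolution: `G∗(I·M) / G∗M` with the binary lung
  mask M, so out-of-mask voxels carry zero weight and a constant image is
  exactly constant inside any mask.
- Derivatives apply derivative-of-Gaussian kernels at the same σ to the
  mask-infilled image (raw values inside M, normalized-convolution
  estimates outside). This keeps every channel at a single smoothing scale;
  the alternative reading — derivative kernels on the already-smoothed
  image — would put derivative channels at σ√2. Whether the original
  formulation mask-normalized its derivatives is unknowable from the
  description; this choice is documented, not asserted as anyone else's.
- The truncated second-derivative kernel does not sum exactly to zero
  (Σ taps ≈ −8.7e−5 at 4σ); that DC leakage, multiplied by ≈ −850 HU,
  would fake a ~0.2 Laplacian on constant tissue, so it is subtracted from
  pure second derivatives.
- Hessian eigenvalues are sorted by signed value, λ1 ≥ λ2 ≥ λ3, computed by
  the closed-form trigonometric solution for symmetric 3×3 matrices
  (vectorised; ~10× faster than batched LAPACK at 41³, max error vs
  `eigvalsh` ~5e−15). Gaussian curvature is det H = λ1λ2λ3 and eigen
  magnitude is the Frobenius norm √(λ1²+λ2²+λ3²), following the customary
  filter-bank feature set for lung texture.
- Adaptive binning: interior edges at the j/10 quantiles of pooled
  responses from *reference* subjects disjoint from any train/test subject
  (outer edges ±∞); all-equal reference samples raise. Histograms (10 bins
  per filter × scale) are normalized to sum 1; ordering is scale-major,
  then filter, then bin.
- `VolumeGaussExtractor` computes responses once per subject volume and
  histograms patch windows, which is both faster (overlapping patches and
  slice-map grids share responses) and cleaner (no patch-border artifacts);
  the per-patch `gauss_features` path remains for standalone use.

## Phantom simulator

What it emulates: the LAA contrast that density masking and texture
classifiers must detect — correlated Gaussian parenchyma around −850 HU
(SD 40 HU, correlation length 1.5 mm) inside an ellipsoidal lung, spherical
lesions around −975 HU (SD 15 HU) planted at uniform in-lung centers until
a target fraction of the lung is lesioned. Defaults: 128³ voxels at 0.6 mm,
burden 0.15, lesion radii 12–18 mm. The final blob's radius is capped so a
single sphere cannot overshoot the target by more than ~30 % of the
remaining volume, keeping realized burden within a few points of target.
Radii are large relative to clinical emphysema lesions by design: a
desk-scale lung is only ~65 mm across, and with many small lesions every
41³ patch would intersect lesion tissue, making instance-level evaluation
vacuous.

Covariates use fixed noisy decreasing links,
`dlco_pct = 85 − 180·burden + ε` and `fev1_pct = 95 − 200·burden + ε`,
ε ~ N(0, 8), clamped positive. Healthy subjects thus center near
DLCO 85 % / FEV1 95 %; diseased subjects at burden 0.15 center near
DLCO 58 % — deliberately straddling the 60 % threshold so the `dlco`
channel is a *noisy* labeling (as in practice) while `copd` aligns exactly
with the presence of lesions. GOLD classes for diseased subjects come from
fixed FEV1 bands (≥70 A, ≥55 B, ≥40 C, else D); a cohort-quartile
assignment would need the whole cohort at generation time and buys nothing
for testing. All randomness flows from one seed through
`numpy.random.SeedSequence` spawns, so subjects, cohorts and the whole
pipeline are bit-reproducible.

What it does **not** emulate — and what a green test therefore cannot
establish: airway/vessel anatomy, respiratory motion, scanner
reconstruction kernels, inter-scanner intensity shifts, mild/diffuse
emphysema phenotypes, or clinically realistic GOLD distributions. Perfect
bag AUC on phantoms says the machinery works, not that clinical
performance would be perfect.

## Pipeline conventions

- Patch sampling: uniform over valid centers (center in mask, full patch
  inside the volume), with replacement; per-subject seeds spawn from the
  master sampling seed and never depend on the label channel.
- Nested CV: subject-level stratified folds (a subject's patches never span
  folds); inner selection maximizes mean inner-fold bag AUC with larger
  mean Separability breaking ties (the two metrics are stated as jointly
  desirable without a combination rule; lexicographic is the least
  arbitrary). Separability on held-out bags uses their true labels and is
  reported alongside the training-bag variant.
- Slice maps: axial slices containing lung, minus the top and bottom 10 %
  (the "top/bottom of the lungs" exclusion is unquantified; 10 % is fixed
  and configurable), then `n_slices` slices at the configured spacing,
  centred in the eligible range. Grid points are every `voxel_stride`-th
  voxel in both in-plane directions inside the mask. Points whose patch is
  clipped by the volume border are kept only if ≥ 50 % of the clipped
  window is in-mask. All grid points of a subject form one pseudo-bag so
  MILES-Q's bag-context instance scoring is well defined. % emphysema uses
  grid points as the denominator (matching the sampling protocol; counting
  all lung voxels would mix sampled and unsampled space) and the 0.5
  posterior threshold is strict (0.5 exactly → healthy).
- Display scaling: AUC and S are averaged unscaled across folds and shown
  ×100 in summaries.

## Statistics

- Spearman: average-rank ties; exact permutation p for n ≤ 7 (all n!
  pairings, vectorisable at that size), t approximation above.
- Fisher r-to-z: `z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))`,
  two-sided normal p.
- LAA% counts voxels strictly below the threshold (−950 HU default).
- Dice of two empty masks is 1 by convention (perfect vacuous agreement).

## Known limitations

- The imputation heuristic in miSVM-Q has no optimality guarantee; on
  barely separable data it can settle in a different local optimum than
  exhaustive search (observed on toy data with heavily overlapping
  concepts).
- Desk-scale phantoms make 41³ patches large relative to the lung, so
  posterior slice maps saturate toward positive in diseased phantoms;
  localization quality (Dice vs planted lesions ≈ 0.35) is bounded by the
  patch/lesion size ratio, not by the classifier alone.
- MILES-Q's effective sample size is the number of subjects, so at
  desk-scale cohort sizes it is markedly more variance-prone than miSVM-Q
  (consistent with its lower reported performance at clinical scale).
- The default hyper-parameter grid (8 kernels × 7 C × 5 q) is exposed but
  compute-heavy; tests and examples use documented reduced grids that span
  kernel bandwidth, C and q.
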