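# Methods

`radscav` implements a voting scheme for ensembles of probabilistic
classifiers on class-imbalanced binary problems — Selective Class
Average Voting (SCAV) — together with the surrounding machinery of a
radiogenomics experiment: radiomic feature extraction from segmented
tumor volumes, filter-style feature selection, SMOTE class balancing,
a leakage-free cross-validated classifier harness, and the evaluation
metrics. A synthetic-data module supplies imbalanced feature tables,
correlated model-score banks and textured ellipsoidal tumor volumes
with known ground truth, so that every stage is testable end to end
without access to a clinical cohort.

## The voting model

The substrate of all voting is an m x n score matrix `P`, where
`p_ij` in [0, 1] is model i's *pseudo-probability* (an uncalibrated
score) that sample j belongs to the minority class. Throughout, the
minority class ("mutant") is the positive class.

**Average voting** scores each sample by `mean_i p_ij` and labels it
minority iff the mean reaches 0.5. **Maximum voting** defers, per
sample, to the single most confident model (confidence
`max(p, 1-p)`, ties to the lowest model index) and adopts its score.

**SCAV** addresses the failure mode of average voting at 14-24%
prevalence: classifiers fit to a rare-positive cohort emit minority
scores that sit mostly below 0.5, so a handful of confident minority
votes is washed out by a sea of indifferent majority scores and
sensitivity collapses. SCAV instead:

1. counts the models voting minority (`p_ij >= 0.5`), giving `v_j`;
2. if `v_j >= t` for a count threshold `t`, labels the sample
   minority and scores it by the mean of the *minority-voting*
   models' scores; otherwise labels it majority and scores it by the
   mean of the majority-voting models' scores;
3. applies a final 0.5 cut to the score, which under these
   conventions provably reproduces the branch decision (the minority
   branch averages values >= 0.5, the majority branch values < 0.5).

Conventions that were genuinely open and are fixed here, with reasons:

* "count reaches the threshold" is `v >= t`, so `t = 1` is the
  any-vote rule and `t = m` demands unanimity; a strict `>` is the
  same family shifted by one, so no generality is lost.
* A model's tie at exactly 0.5 votes minority — conservative for the
  rare class.
* The majority-branch average is still the *minority*-class
  pseudo-probability of the majority-voting models, keeping one score
  axis so ROC analysis of the ensemble score is meaningful. Averaging
  majority-class probabilities instead and complementing gives the
  same ordering, so nothing hinges on this choice.

**Threshold tuning.** `t` is selected on training data only: every
`t` in `1..m` is evaluated and the one maximizing the training AUC of
the SCAV ensemble score is kept, ties to the smallest `t`. Inside the
cross-validated experiment the tuning objective is the mean of
fold-training AUCs, and test rows never enter it.

**Member selection.** Base models are ranked by their mean
fold-training AUC and the top k (5/10/20 typical) form the ensemble;
ties keep the lower model index, and the ordering is stable.

## The tabular experiment

`run_cv` runs stratified k-fold cross-validation (default 10-fold)
over a grid of base-model configurations — feature ranker (rank-sum
test or ReliefF) x feature-set size (5/10/15/20) x learner (random
forest, SVM, gradient boosting, neural network) = 32 configurations —
with the stage order *selection -> SMOTE -> fit* applied within each
fold's training rows only. Folds are stratified because at 14%
prevalence unstratified tenths of an 83-sample cohort would often
contain no minority case. Pooled out-of-fold scores form the
ScoreMatrix that the ensemble stage consumes; per-configuration mean
fold-training AUCs drive member ranking.

Learners are deliberately thin adapters over scikit-learn estimators
with default-style hyperparameters (scaling added for the margin- and
gradient-based ones, a seed bound for determinism): the method under
study is everything around them. A trivial deterministic
"mean" adapter (sign-aligned standardized feature mean through a
logistic) exists for fast tests and smoke runs.

### Feature ranking

* **Rank-sum (Mann-Whitney)**: two-sided p-value per feature between
  the classes, ascending order. Exact p-values for small tie-free
  samples, tie-corrected normal approximation otherwise (scipy's
  `auto` policy). Constant features get p = 1.
* **ReliefF**: a deterministic all-instances variant. Features are
  range-normalized; every instance contributes
  `sum |diff to its n nearest misses| - sum |diff to its n nearest hits|`
  per feature, normalized by `n_samples * n_neighbors`
  (n_neighbors = 10 by default, reduced when a class is small).
  Determinism (no instance sampling, index-ordered distance ties)
  makes selections exactly reproducible; packaged ReliefF
  implementations differ mainly by sampling, which only adds noise.

Both rankers break score ties lexicographically by feature name, so a
ranking is a pure function of the training table.

### SMOTE

Synthetic minority samples are `x_i + g (x_nn - x_i)`, `g ~ U(0,1)`,
with `x_nn` one of the k = 5 nearest minority neighbours of `x_i`
(Euclidean distance on features standardized by the training table's
mean/sd; synthetic values are mapped back afterwards — an affine
round-trip, so every synthetic point lies exactly on a segment
between two originals). Synthesis cycles over minority bases until
the minority count reaches `target_ratio` (default 1.0) times the
majority count, within one sample. Only oversampling is performed;
no majority undersampling. Original rows pass through bit-identically
and synthetic rows are flagged, so downstream code can always exclude
them (training-AUC computation does).

### Metrics

Accuracy, sensitivity and specificity come from the 2x2 table with
mutant positive. On a degenerate fold (single-class truth) the
undefined ratio is reported as NaN with a warning, never coerced to
0 — silently optimistic reports on degenerate folds are a real
failure mode of imbalanced pipelines. AUC is the normalized
Mann-Whitney U statistic (ties get half credit), which equals
trapezoidal ROC integration exactly.

## Radiomic features

All texture and shape formulas follow community-standard (IBSI-style)
definitions, stated in the docstrings; 146 features in six families:

* **Histogram** (5): mean, population sd, 10th/50th/90th percentiles
  (linear interpolation between closest ranks) of masked intensities.
* **GLSZM** (3): grey levels are discretized inside the mask into 32
  equal-width bins (a constant region maps to level 1); connected
  zones use 26-connectivity in 3D / 8 in 2D. Features: grey-level
  variance, small-zone low-grey-level emphasis, grey-level
  non-uniformity.
* **GLRLM** (1): run-length matrices per direction (13 unique 3D
  directions, 4 in 2D; mask gaps break runs), grey-level
  non-uniformity averaged over directions.
* **Laws** (125): all outer products of the 1D kernels
  {L5, E5, S5, R5, W5} applied separably with reflective boundaries;
  energy = mean absolute response over the mask.
* **Wavelet** (8): one-level separable 3D Haar decomposition
  (periodization mode); energy = mean squared coefficient per subband
  over the block-reduced mask region.
* **Shape** (4): from the covariance eigenvalues `l1 >= l2 >= l3` of
  spacing-weighted voxel coordinates, flatness = `sqrt(l3/l1)`;
  asymmetry = `1 - sqrt(l2/l1)` of the largest-area axial slice's 2D
  covariance (kept two-dimensional so it measures cross-section
  eccentricity, distinct from flatness); orientation = angle in
  [0, 90] degrees between the major eigenvector and the z axis;
  surface-to-volume ratio in physical units.

Surface area is measured on the marching-cubes isosurface of the mask
(scikit-image) rather than by counting exposed voxel faces: face
counting overestimates the area of any smooth body by large factors
(6pi r^2 instead of 4pi r^2 for a sphere, a 50% error in
surface-to-volume), while the mesh estimate is within a few percent
at the sizes used here.

Because quantization happens inside the mask over the observed range,
all texture features are invariant to intensity shifts; Laws energies
are 1-homogeneous and wavelet energies 2-homogeneous in intensity
scale — properties the tests assert.

## The image branch

`select_slices` picks up to three 128 x 128 tumor ROIs per volume:
the axial slice with the largest mask area (ties to the lowest z) and
the slices two steps above and below it — immediately adjacent slices
are skipped as near-duplicates — dropping a candidate whose area
falls below 10% of the central area (no clear piece of tumor; both
the offset and the fraction are configurable). Crops are centered on
the slice's mask centroid and constant-padded at volume borders.

`grouped_split` assigns whole patients to train/validation/test
(default 65/15/20) so that multiple slices of one patient can never
straddle a split. Split sizes follow largest-remainder rounding; the
minority class is stratified, and whenever minority patients number
at least the number of splits, every split receives at least one.

## Synthetic data: what it emulates, and what it does not

* **Feature tables**: class-conditional Gaussians. Informative
  features shift their mean by `effect_size` (in sd units) for mutant
  samples; the rest are label-independent N(0,1). The minority count
  is exactly `round(n * minority_fraction)`; defaults follow the
  study conditions (83 samples, 266 features, prevalence 0.14 for the
  EGFR-like case, 0.24 KRAS-like). One synthetic patient per sample
  in the tabular branch.
* **Score banks**: `p_ij = logistic(d * u_j + e_ij)` with shared
  latent `u_j = log(pi/(1-pi)) + 1{minority}` and per-model noise
  `e ~ N(0, noise_sd)`. The latent is the class indicator anchored at
  the prior log-odds, reflecting how classifiers trained on
  rare-positive cohorts score: mostly below 0.5, crossing it only for
  clear minority cases. This is the regime in which average voting
  loses sensitivity and selective voting recovers it; a latent
  symmetric about zero would hand average voting an unrealistically
  high sensitivity and mask the phenomenon. Model diversity is one
  knob (noise sd), per-model strength another (discrimination); with
  zero noise each model ranks perfectly, with zero discrimination
  every score is exactly 0.5.
* **Tumor volumes**: a discretized ellipsoid mask with a uniform
  soft-tissue base intensity plus Gaussian texture inside and an
  air-like constant outside.

What the generators deliberately do not model: feature correlations
within real radiomic families, acquisition physics and resampling
artifacts, inter-model correlation structure beyond one shared
latent, multi-lesion patients, clinical covariates. Passing tests
therefore certify the algorithmic contracts (voting identities,
leakage-freeness, monotonicity, geometry) and the qualitative
imbalance phenomenon, not clinical performance on CT cohorts.

## Numerical choices and degenerate inputs

* Quantization uses `floor(n_levels * (v - min)/(max - min)) + 1`
  clipped to `n_levels` (maximum maps to the top level; constant
  regions to level 1).
* Distance ties in ReliefF and SMOTE neighbour search break on sample
  index; score ties in member ranking on model index; threshold ties
  on the smallest t; ranker score ties lexicographically on feature
  name. Every tie rule is deterministic and documented where it acts.
* Sub-seeds for folds, configurations and SMOTE derive from the
  top-level seed via `numpy.random.SeedSequence`, so one seed pins
  the whole experiment; repeated runs are byte-identical.
* Degenerate folds (single-class truth) yield NaN ratios with a
  warning; empty masks, sub-kernel volumes, single-class tables,
  out-of-range thresholds and undersized minorities raise
  `ValueError` at the boundary rather than propagating nonsense.

## Problem sizes

Defaults target cohort-scale inputs (tens to hundreds of samples,
tens-of-voxels tumors). The test suite and the acceptance script use
reduced grids — e.g. 5-fold cross-validation over 8-16
configurations on 80-200 samples, 1,000 random score matrices for
oracle agreement, 100 random 6x6x6 grids for the zone-count
cross-check, a 1,000-sample score bank for the selective-voting
comparison — sizes at which every checked property is stable across
seeds while the full run stays in the minutes range on one CPU.

## Known limitations

* Asymmetry and orientation have no canonical radiomics definition;
  the eigenvalue-based definitions here are stated substitutes and
  should not be compared numerically across packages.
* SCAV's ensemble score is a within-branch average; it orders samples
  well enough for threshold tuning but is not a calibrated
  probability, and AUC computed on it mixes two score regimes.
* The deterministic ReliefF variant weights all instances equally;
  with heavy feature redundancy its weights compress relative to
  sampled variants.
* `select_threshold` optimizes AUC as specified; when the operating
  point matters more than ranking (e.g. sensitivity at fixed
  specificity), tuning t against that metric directly is the better
  choice and is a one-line change at the call site.
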