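# Methods

`mmstack` evaluates how much multimodal feature integration a brain-based
behaviour prediction needs. This note records the model, the protocol, the
defaults and the design choices, in the package's own terms.

## Prediction protocol

**Cross-validation.** All models in a run share one family-aware repeated
k-fold scheme (default 10 repeats × 10 folds). Whole families are assigned
to folds greedily — families shuffled per repeat, placed largest-first into
the currently smallest fold — so siblings never straddle a train/test
boundary and fold sizes differ by at most roughly the largest family.
Sharing the scheme makes fold-wise accuracies of any two models paired.

**Confounds.** The confound design is the 8-vector
[age, age², gender, age·gender, age²·gender, handedness, brain size, ICV],
gender coded 1=female / 2=male. For feature-wise models the target is
residualised against this design with ordinary least squares fitted on the
training split only (`confound_mode="target"`, the default); a
`"both"` mode additionally residualises the features. The confound model
uses the 8 confounds as features with no residualisation. The choice of
target-only deconfounding as default is a genuine open point: the
protocol's wording fixes only that deconfounding happens in-fold; both
sides are implemented.

**Feature-wise models.** Elastic net per block per fold. Features are
z-scored with training-fold statistics (zero-variance columns pass through
unscaled) — without this the penalty is not comparable across columns. The
L1 ratio and α are selected by an inner family-aware 5-fold grid search
minimising mean squared error; defaults L1 ∈ {0.1, 0.5, 0.7, 0.9, 0.95, 1.0},
α log-spaced 1e-3…1e1 (10 values). The inner CV of the selected
combination doubles as the source of **nested training predictions**: each
training subject's value comes from the inner model that did not train on
it. Inner models re-standardise on their own inner-training rows; the
target residualisation stays at the outer-fold level (the inner CV selects
hyperparameters and produces meta-features, it does not redo the
deconfounding). Single-combination grids skip the selection loop when no
nested predictions are requested.

**Accuracies.** Pearson correlation between predicted and observed values,
and the coefficient of determination COD = 1 − SS_res/SS_tot about the
observed mean (scikit-learn's `r2_score`; can be negative). A
zero-variance prediction vector is assigned correlation 0 rather than NaN,
so fold means stay defined; a zero-variance *observed* vector is an error.

**Stacking.** Per fold, all models (confound model included) are ranked by
training-split accuracy computed from the nested predictions; exact ties
break alphabetically. For level k the top-k models' predictions form the
meta-feature matrix (training rows = nested predictions, test rows =
outer-fold predictions, columns in ranking order). The meta-learner is a
Random Forest regressor (`criterion="squared_error"`, identical to MSE
with Friedman's improvement score for regression forests), tuned by an
inner 5-fold grid search; defaults trees {100, 500}, max depth
{None, 2, 5, 10}, max features {all, √P, 1/3}. "Minimum depth of trees"
in the protocol's hyperparameter list is read as a depth-control knob and
implemented as maximum depth. The stacked model predicts the residualised
target, matching the feature-wise models it stacks; the confound model's
column enters on its own raw-target scale, which a forest handles without
rescaling. Level 1 is defined as the per-fold top-ranked base model, making
the series complete from 1 to F. One RF seed per (repeat, fold, level) is
derived from the run seed via `numpy.random.SeedSequence`, so parallel
execution cannot change results.

**Saturation inference.** Fold-wise accuracies overlap in their training
sets, so a naive paired t-test over folds badly over-rejects. The corrected
resampled t-test inflates the variance:

    t = d̄ / sqrt((1/J + n_test/n_train) · s²),   df = J − 1,

with J = repeats × folds and s² the sample variance of the paired fold
differences. Because family constraints make folds slightly unequal, the
ratio uses average fold sizes n_test = N/k, n_train = N − N/k. Degenerate
s² = 0 gives t = 0, p = 1 when d̄ = 0 (and p = 0 otherwise). All level
pairs are tested two-sidedly and corrected with Holm by default
(Bonferroni, Benjamini–Hochberg and no correction are available; the
correction actually used upstream is not identifiable, and Holm is the
conservative family-wise default). The **best** level maximises mean
accuracy (lowest level on ties); the **necessary** level is the smallest
level ≤ best with corrected p ≥ α (default 0.05) against the best.
"Statistically comparable" is thus non-rejection, not equivalence — a TOST
equivalence test is deliberately out of scope, and the caveat is that
non-rejection at small J is weak evidence of equality. Best and necessary
sets are computed per metric. The validity filter keeps targets whose
necessary-level mean COD is strictly positive.

## Feature derivations

All subject-level derivations are pure functions; both group-level
derivations follow a fit/apply split so they can run inside CV without
leakage (a fold-wise block wrapper refits them per fold).

- **Model-free FC**: Pearson correlation of region timeseries, upper
  triangle, Fisher z with r clamped to ±(1 − 1e−7); constant regions are
  an error naming the region.
- **Time-varying FC**: VAR(1) least squares x_t ≈ A·x_{t−1}; the lagged
  and lead windows are demeaned separately (equivalent to an intercept),
  which makes the noiseless case exact; full R×R matrix returned;
  rank-deficient designs error with a ridge (λ = 1e−6) fallback option.
- **Network statistics**: on the negative-clipped weighted graph (absolute
  value mode available), characteristic path length and global efficiency
  on 1/weight lengths, maximum-modularity communities (exact enumeration
  up to 8 nodes, where heuristics demonstrably miss the optimum; seeded
  Louvain restarts beyond), and participation coefficients against that
  partition.
- **Gradient loadings**: diffusion map of the training-average FC — rows
  sparsified at the 90th percentile, nonnegative cosine affinity,
  anisotropic normalisation α = 0.5, row-normalised diffusion operator,
  10 components by default; eigenvector signs fixed by forcing the
  largest-magnitude entry positive. Out-of-sample subjects are embedded by
  a Nyström-style kernel projection against the training reference rows;
  projecting the training-average FC reproduces the template loadings.
  The upstream parameterisation is not published; these values are common
  practice and configurable.
- **Morphometry normalisation**: SA/ICV^(2/3), GMV/ICV, CT/mean(CT).
- **Morphometric covariance**: per-region training mean/sd; a subject's
  edge (i,j) is the z-score product z_i·z_j, whose training mean equals
  the training Pearson correlation up to (n−1)/n. This z-score-product
  definition is an approximation of covariance-style "anatomical
  connectivity" tools, which publish no closed form; zero-variance regions
  are flagged and their edges zeroed.

## Synthetic cohorts

The generator emulates what the pipeline sees, not raw images: no
scanner noise, hemodynamics, surfaces or missing data.

- Family sizes are truncated-geometric (p = 0.5, max 5), mirroring
  sibship-heavy cohorts. Age uniform over a configurable range,
  handedness bimodal (90% right), ICV and brain size positively correlated
  with a male shift — enough structure that confound regression is
  non-trivial.
- Blocks are standard-normal matrices of two shapes: vectorised
  connectivity upper triangles (P = R(R−1)/2) and region maps. A single
  latent trait is injected into each informative block through a sparse
  column pattern — rank-1 over region pairs for connectivity blocks, so
  the planted signal stays low-rank and solvable at P ≫ N. The
  block-expressed scores have pairwise correlation `latent_sharing`
  (default 0.5; 0 = fully complementary blocks, near 1 = redundant).
  Because each expressed score is an exact linear combination of realised
  block columns, the manifest records columns, coefficients, centring and
  weights, and reproduces the target to machine precision at zero noise.
- Target = planted signal (variance fraction `signal_r2`) + standardised
  confound combination (fraction `confound_r2`, built from age, gender,
  ICV) + Gaussian noise (remainder); a Student-t (df 5) noise switch
  exists but is off by default. Planted effect sizes are free parameters
  of the generator — no external calibration for them exists.
- Timeseries are stationary VAR(1) with A = a·I (|a| < 1 enforced via the
  spectral radius) and community-structured innovation correlation; the
  generating A and covariance are recorded for tests.

Passing tests on these cohorts shows the machinery is leakage-free and
recovers planted structure; it does not certify accuracy levels on real
cohorts, whose noise is neither Gaussian nor independent across blocks.

## Evaluation studies and problem sizes

The studies in `mmstack.studies` (run by the test suite and
`scripts/acceptance.py`) use desk-scale sizes chosen so a full pass runs in
minutes on one CPU while keeping every protocol step intact: compact
blocks (connectivity R = 10–12, region maps P = 30–40), the study grids
L1 = 0.5 with α ∈ {0.01, 0.1, 1.0} and a single RF configuration
(50 trees, depth 3).

- **Statistical oracles**: the corrected t formula against an independent
  direct evaluation on 1000 random inputs; Holm against a hand-stepped
  step-down oracle on all 3-element p-sets over an 8-point grid.
- **Calibration**: two equally informative blocks (N = 300, 2×5 CV,
  200 replicates). Every rejection is a false positive; the corrected
  rate should sit near α while the naive paired t over-rejects — the
  reason the correction exists.
- **Recovery**: signal planted in m ∈ {1, 2, 3} of 6 blocks, joint
  R² = 0.4, sharing 0.5, 1×10 CV, 20 runs per m; median necessary level
  and the fraction of runs where every planted block out-ranks every noise
  block in top-m composition frequency. (At these sizes the corrected
  test is conservative and the necessary level is typically 1; the top-m
  frequency is therefore the informative recovery readout.)
- **Leakage battery**: 50 target permutations at N = 200 over a 3-block
  cohort; every model class — feature-wise, confound, stacked at every
  level — must score mean COD ≤ 0 within its Monte-Carlo CI, plus a
  bit-level check that scrambling held-out subjects leaves the
  training-side fit unchanged.
- **Curve shape**: complementary signal (sharing 0) in 3 of 6 blocks,
  joint R² = 0.6, N = 200, 2×5 CV: the curve should rise beyond the best
  single block and not collapse after its peak, with necessary ≤ best.

## Known limitations

- The corrected resampled t-test is conservative; at J = 10 the necessary
  set is biased small. A full-cohort setting (10×10 CV, N ≈ 600–800) has
  materially more power; the defaults target that scale, the studies run
  desk-scale.
- Non-rejection ≠ equivalence (no TOST).
- Effective connectivity, tractography-based connectomes and DTI maps
  enter only as precomputed blocks; their estimation is out of scope.
- Louvain above 8 nodes is a heuristic: modularity is a lower bound on the
  optimum.
- The generator's Gaussian blocks cannot exhibit real-data pathologies
  (site effects, motion artefacts, heavy-tailed outliers beyond the
  Student-t switch, block-correlated noise).
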