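# Methods

## Normalization model

Both normalizers operate gene-by-gene (column-separable) and see only the
*target* matrix — the training distribution — never test labels. This
mirrors how they are used inside supervised learning: the target is the
data the classifier was trained on, and the test fold is mapped onto it.

**FSMVN.** For gene *j* with test column *x* and target column *y*:
`x_norm = (x − x̄)/s_x · s_y + ȳ`, with sample standard deviations
(denominator n−1, the convention of the R ecosystem where this method
originated). The output column's mean and SD equal the target's exactly
(to ~1e−15 in floating point). The map is affine and strictly increasing,
so within-gene sample ranking is preserved and any affine platform
distortion is inverted exactly.

**FSQN.** For gene *j*, the test column's empirical distribution is
replaced by the target column's. With equal counts this is the exact
order-statistic exchange (no interpolation is performed, so sorted output
equals sorted target bitwise). With unequal counts, the sorted target is
interpolated linearly at the test plotting positions (i−1)/(n−1) — the
type-7 quantile convention, chosen to match the de-facto reference
implementation of target-quantile normalization. Tied test values receive
the mean of the values their positions map to, so ties stay tied and
Spearman correlation with the input is 1 up to ties.

**Degenerate rules.** A zero-variance (constant) test gene maps to the
target column mean under FSMVN and to the target column median under FSQN,
with a warning rather than an error: small cross-validation folds of real
filtered matrices do contain near-constant genes, and failing the whole
fold for one such gene would be worse than the documented fallback. A
zero-variance *target* gene yields the constant target value (warned).

## Synthetic paired cohorts

The generator stands in for the gold-standard design: the same biological
samples measured on two technologies. Latent signal
`z_ij = m_j + effect_ij + N(0, biological_sd²)` with per-gene baselines
`m_j ~ N(7, 2²)` (typical log2-abundance location and spread).

* **Subtype structure.** K classes with imbalanced proportions (default
  0.4/0.3/0.2/0.1, as in real subtype label sets). A fraction (default
  10%) of genes are signature genes, assigned round-robin to classes; each
  carries a ±1.5 log2-unit mean shift in its class. Effects are *signed*
  with a class-specific up/down balance, evenly spaced from all-up to
  all-down across classes. The asymmetry is deliberate and load-bearing:
  real subtype programs are unbalanced, and for a margin classifier the
  per-class score offsets induced by platform distortion are weighted sums
  of its coefficients — with perfectly balanced signatures those offsets
  cancel between classes and raw cross-platform transfer would (unrealistically)
  succeed no matter how strong the distortion.

* **Platforms.** Platform A observes `z` plus `N(0, noise_sd²)` — a
  log-abundance technology (RNA-seq-like). Platform B observes
  `a_j + b_j(z − c·m_j) + s·h(z − c·m_j)` plus its own noise: per-gene
  location shifts `a_j ~ N(0, shift_sd²)`, scale factors `b_j` uniform on
  a positive interval (default 0.5–2), and a centering fraction `c`
  (default 1) that makes platform B a *ratio-type* technology reporting
  values near 0 per gene — the two-colour microarray log-ratio convention.
  The coherent displacement of every gene by its own baseline is the
  realistic failure mode for raw transfer: a classifier's decision values
  evaluated far outside the training cloud collapse to a constant
  prediction. `h(u) = 4·tanh(u/4)` is a fixed smooth monotone saturation
  (array-like dynamic-range compression); its strength defaults to 0 so
  that the base distortion is affine and FSMVN's inversion can be exact,
  with the nonlinear case available as a stress test. Every `g_j` is
  strictly increasing, so FSQN can invert the platform effect in principle
  (exactly, in the absence of noise and with equal sample counts).

* **What a green test does not establish.** The generator draws genes
  independently (no co-expression), uses Gaussian noise, one global effect
  size, and distortions independent of expression level beyond the
  centering term. Real data add correlated programs, heteroskedastic
  noise, missing genes between platforms, and label noise; results here
  validate the machinery, not any specific real-data effect size.

* **Randomness.** All draws flow from one seed through
  `SeedSequence.spawn` children consumed by counter-based (Philox)
  generators, one stream per component, so the draw for one component
  cannot perturb another.

## Evaluation harness

Nested stratified cross-validation: outer k=10 estimates performance,
inner k=5 tunes hyperparameters (and the LASSO penalty during selection).
The two inner layers a three-layer design would distinguish (tuning vs
training of feature-selected models) are collapsed into one tuning loop —
the outer layer drives every reported metric, and the collapse only
affects how well-tuned each fold's model is. Within each outer fold:

1. the training distribution is the training platform minus the held-out
   fold;
2. optional feature selection on that data only — either LASSO
   (L1 multinomial logistic over a descending penalty grid, penalty with
   minimal mean cross-validated deviance, genes with any nonzero
   coefficient; features standardized as glmnet does) or per-class ROC
   variable importance (per gene, AUC of the gene alone for the class,
   folded as max(AUC, 1−AUC); top ⌈count/K⌉ per class, union,
   dedup — so achieved counts are approximate). When LASSO sizes the SVM
   selection, the mean selected count across outer folds is used, rounded;
3. the classifier is tuned and fitted on the (feature-reduced) training
   distribution. `svm_linear` is a linear-kernel libsvm SVC with cost grid
   {0.01, 0.1, 1, 10}; `glmnet` is elastic-net multinomial logistic with
   mixing {0.1, 0.55, 1.0} × 10 log-spaced strengths, standardized inside
   the pipeline. Tuning maximizes balanced accuracy;
4. four test sets are built from the held-out samples: same-platform
   reference, raw other-platform values, and FSQN/FSMVN of the
   other-platform values onto the training distribution — normalization
   applied *after* restriction to the selected genes;
5. metrics per condition: balanced accuracy in the
   (sensitivity+specificity)/2-per-class-then-average convention (chance
   level 0.5 for any K; classes with no true members are excluded with a
   warning), Cohen's kappa from the confusion-matrix marginals, and MASE
   per gene, `mean|x̂−y| / mean|y−ȳ|`, averaged over genes (cross-platform
   conditions only — the reference has no paired counterpart to normalize;
   constant-reference genes are excluded with a warning).

Fold assignments are deterministic from (labels, k, seed) and shared
across conditions, models and selection methods, so all comparisons are
paired. Nothing derived from a held-out fold — selection, tuning,
normalization target — can touch the trained model; the test suite
verifies bit-identical models after planting an extreme outlier in a
held-out fold.

## Statistics

* Bootstrap CIs: percentile intervals from 1,000 resamples of *fold-level*
  metric values (the plotted unit of a CV benchmark), seeded.
* Kruskal–Wallis with midrank tie correction; Dunn's (1964) pairwise z
  tests with the pooled tie-corrected rank variance
  `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal p-values,
  Holm-adjusted across pairs.
* OLS with treatment (reference-level) coding and classical standard
  errors; estimated marginal means average model predictions over the
  cartesian grid of the other factors' levels with equal weights; pairwise
  contrasts use Wald t tests on the coefficient covariance with Holm
  adjustment. A saturated fit with numerically zero residual variance is
  treated as exact: a zero contrast gets p = 1, a nonzero one p = 0,
  instead of dividing float noise by float noise.
* Platform mixing is scored as the mean silhouette width of platform
  labels on the first two PC scores (PCA by SVD of the centered matrix) —
  a separation claim made visually in the literature, turned into a
  testable number. Density overlap is ∫min(f_X, f_Y) of Silverman-bandwidth
  Gaussian KDEs of all pooled values on a shared grid padded by three
  bandwidths.

## Numerical choices and limitations

* FSQN equal-count exactness is bitwise by construction (no interpolation
  path is taken); FSMVN moment exactness is ~1e−15 relative.
* `ols_fit` refuses rank-deficient designs rather than silently dropping
  aliased terms; `marginal_means_contrasts` requires a balanced factor
  grid only for the equal-weight averaging to equal raw means.
* The default experiment sizes (200 samples × 2,000 genes, outer k=10)
  run in seconds on one CPU; they are a desk-scale surrogate for cohorts
  of hundreds of samples × ~13,000 genes, not a reproduction of any
  real-data result.
* Distribution-level quantile normalization, training-distribution
  matching, probe-to-gene mapping and subtype label calling are out of
  scope; labels are inputs.
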