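# Methods

This note records the modelling and numerical choices behind `aesurv`,
what the synthetic data does and does not emulate, and the known
limitations of the approach.

## Preprocessing

The two-step normalization is MAD-based feature filtering followed by
per-feature scaling.

* **MAD filter.** A feature is kept when its MAD (median of absolute
  deviations from the feature median, unscaled) *strictly* exceeds
  `min_mad` (default 0, i.e. only constant features are dropped).  A
  `top_k`-by-MAD option provides harder variance filtering.  Filtering
  before scaling guarantees the scaler never sees a zero-spread feature.
* **Scaling.** `CohortScaler` is mode-agnostic: `robust` (default) stores
  median and interquartile range, `standard` stores mean and population
  SD.  Quantiles use linear interpolation (the numpy default), fixed for
  reproducibility.  Whatever the mode, validation data is always
  transformed with the statistics fitted on the training cohort — scaling
  a validation cohort by its own statistics would leak information and
  silently absorb cohort shifts.
* **Unit squash.** The autoencoder's logistic reconstruction loss needs
  inputs in [0, 1], so each feature is min-max mapped into
  [ε, 1−ε] (ε = 0.01; constant features map to 0.5).  On new data the
  training minima/maxima are reused and the result clipped back into the
  band.  The squash is specific to the autoencoder path; the PCA baseline
  and the SVM consume the robust-scaled matrix directly.

## Autoencoder

Architecture d → 500 → 100 → 500 → d; tanh hidden activations; the
bottleneck (100 units) is the learned representation.  Choices that the
loss formulation forces or leaves open:

* **Output activation.** tanh has range (−1, 1) while the logistic loss
  needs (0, 1); the output layer therefore uses a sigmoid (configurable).
  This is the minimal change that makes the stated objective computable.
* **Loss sign.** The summed cross-entropy term is used with a leading
  minus so the loss is non-negative and minimized at perfect
  reconstruction.
* **Regularization.** L1 (a_w = 1e-4) on every weight matrix; L2 activity
  (a_a = 1e-3) on every layer's activations, *averaged over the batch* so
  the penalty is batch-size invariant.
* **Optimizer.** Plain SGD.  The estimator defaults (lr 1e-6, 10 epochs,
  batch 32, 50% dropout) reproduce the reference configuration but barely
  move the weights at realistic input widths; the pipeline config and the
  test-suite use lr 1e-3 / 20 epochs, which trains visibly while staying
  deterministic.  Both configurations are plain parameters — nothing in
  the code special-cases either.
* **Dropout.** Inverted dropout on hidden activations during training
  only; inference is deterministic.  The activity penalty is applied to
  the dropped activations actually used in the forward pass, which keeps
  the hand-derived gradient exact (it is checked against central finite
  differences to < 1e-4 relative error in the suite).
* **Initialization.** Seeded Glorot-uniform (±√(6/(fan_in+fan_out))),
  zero biases.  With the seed fixed, training is bit-reproducible.
* **Loss floor.** Because the reconstruction term is summed over input
  dimensions, its value is dominated by an irreducible entropy floor
  (outputting 0.5 everywhere costs ~0.69 nats per dimension).  Training
  progress is therefore judged on the smoothed trend of the epoch-loss
  curve, not on a fixed fraction of the initial loss.
* **Divergence.** A non-finite batch loss aborts training with the epoch
  number; there is no silent NaN propagation.

## Univariate Cox screen

The screen fits one proportional-hazards coefficient per latent feature:
Newton–Raphson on the Breslow partial likelihood, vectorized across
features; features are standardized internally for conditioning and
coefficients reported on the original scale.  Convergence tolerance 1e-7
on the Newton step, 60 iterations, steps clipped to ±2.5 (on the
standardized scale).  The p-value is the two-sided Wald test.

Degenerate fits (constant feature, vanishing information) are flagged
unselected with a diagnostic instead of raising.  A *monotone-likelihood*
feature (e.g. a perfect predictor) never satisfies the step tolerance;
it is reported at the iteration cap with its (enormous) Wald statistic
and is selected — the correct behaviour for a feature that separates
survival perfectly.  The implementation agrees with lifelines to ~5
decimals on tie-free data and with scikit-survival (Breslow) under ties;
lifelines' Efron tie handling differs slightly, by design.

## Cluster-number selection and naming

K-means (10 restarts, seeded, greedy initialization) is run for each
k in 2..6.  The Calinski–Harabasz score is the primary criterion;
silhouette is recorded alongside and breaks exact ties, then smaller k.
Latent features enter K-means as emitted — no extra scaling — since all
bottleneck activations already share the tanh range.

Clusters are renamed G1..Gk by decreasing median observed survival time
(ties: larger mean, then larger cluster).  Renaming never changes the
partition.  A singleton cluster is a legitimate subtyping outcome (the
PCA baseline produces one on degenerate inputs); it is the *classifier*
that refuses any class with fewer than two training samples.

## Label transfer and cross-validation

"Ten folds with a 6/4 ratio" is read as Monte-Carlo cross-validation: ten
independent seeded random 60/40 splits (ten disjoint folds cannot give a
40% test share).  Within each split, the per-omic ANOVA-F ranking and the
SVM are fitted on the 60% only — the suite asserts the selection is a
pure function of the training fold.  Splits whose training half misses a
class (or leaves one with a single sample) are redrawn, up to 100 times.

SVM: RBF kernel, C = 1, gamma scaled by feature count and variance
(`scale`), Platt probability outputs (needed for the Brier score), seeded.
Feature matching across cohorts is exact string equality of feature ids,
with expression and methylation kept in separate namespaces internally so
shared gene symbols cannot collide.  External prediction refits the SVM
on the training cohort restricted to the features both cohorts share,
rather than zero-filling missing features.

The risk score is the predicted probability of the poorest-prognosis
class.  With two discovered subtypes this makes the C-index mostly a
two-group statistic: among comparable pairs from the same subtype the
risk is nearly tied, and pairs from different subtypes are ordered by the
group effect alone.  Under a proportional-hazards cohort with a group
hazard ratio around 3 this bounds Harrell's C near 0.75 no matter how
good the classifier is (and RBF decision values saturate away from the
boundary, which costs a bit more).  Real cohorts with near-separated
group survival and heavy censoring of the long-lived group escape this
bound; synthetic cohorts calibrated to a moderate hazard ratio do not.
This is a property of binary-subtype risk scores, not a defect of the
implementation, and the acceptance suite reports it as measured.

## Evaluation metrics

* **Concordance.** Harrell's C by explicit pair logic: a pair is
  permissible when the strictly shorter observed time ended in an event;
  ties in predicted risk count ½.  The implementation matches a
  brute-force pair enumeration exactly on randomized instances with ties
  and censoring.
* **Brier.** Binary flavor: mean squared difference between the predicted
  event probability and the event indicator over observed follow-up.  A
  time-horizon variant (events before t vs known survivors at t, subjects
  censored before t dropped as ambiguous) is available as
  `brier_score_at`; the binary flavor is the default because it requires
  no horizon choice.
* **Log-rank.** k-group observed-vs-expected tally (lifelines), p from
  chi-square with k−1 df.  When a CV fold predicts a single class, the
  fold's log-rank p is recorded as 1 (one group separates nothing).
* **Aggregation.** Mean and sample SD (n−1; a single fold has SD 0) for
  C-index and Brier; geometric mean for log-rank p with p floored at
  1e-300.
* **Covariate tests.** Wilcoxon rank-sum for continuous covariates
  (Kruskal–Wallis beyond two subtypes), chi-square *without* continuity
  correction for categorical ones; entirely-missing covariates are
  skipped with a warning.
* **Model comparison.** Multivariate Cox fits (lifelines, ridge penalizer
  1e-6 for numerical stability with dummy-coded categories) per covariate
  set, reporting the in-sample C-index; non-convergence flags the model
  instead of raising.

## Methylation-driven genes and enrichment

A gene (shared between the two matrices) is a driver when Spearman
r(methylation, expression) across *all* samples is strictly below −0.3
and the between-subtype Wilcoxon rank-sum p is strictly below 0.05.
Boundary values are not flagged — the suite checks this with a
construction whose Spearman correlation is exactly −0.3.  Direction
follows the methylation difference in the poor-prognosis group:
`hypo_up` (hypomethylated, over-expressed in G2) or `hyper_down`.
Spearman is computed as Pearson on ranks, vectorized over genes, and
cross-checked against scipy per gene.

Over-representation uses the one-sided hypergeometric tail
P(X ≥ overlap) after intersecting each gene set (and the query) with the
universe, with Benjamini–Hochberg adjustment across sets.  The universe
defaults to the genes shared between the expression and methylation
matrices after preprocessing — the only membership that is well-defined
offline.

## Synthetic cohorts

`generate_cohort` emulates exactly the structure the pipeline assumes:

* two subtypes (G2 fraction 0.385, matching a 217/563 split) separated by
  `effect_size` = 2 SD in `n_informative` = 100 features per omic;
* a per-sample standard-normal latent severity that loads on the
  informative features (0.5 per feature) and multiplies the log-hazard
  (weight 1.0).  Without it, survival would depend on the binary subtype
  alone and no predicted risk could rank patients within a subtype —
  a degenerate cohort no real study resembles;
* exponential event times with conditional G2/G1 hazard ratio 3 and a
  1000-day baseline scale; independent exponential censoring whose rate
  is solved numerically (per-sample censoring probability
  μ/(μ+h_i) averaged to the target) for a 55% censor rate, typical of a
  combined low/high-grade glioma cohort.  The marginal fitted two-group
  hazard ratio lands near 2.5 because the unobserved severity attenuates
  it — as it does in real cohorts;
* methylation on the logit scale squashed through a sigmoid, so values
  are strictly inside (0, 1);
* planted driver genes: a shared per-gene latent factor enters expression
  and methylation with opposite signs, plus opposite subtype shifts
  (hypomethylated/over-expressed in G2).  The factor loading is solved
  from the target Spearman correlation via the bivariate-normal relation
  ρ = 2 sin(πρ_s/6), accounting for the covariance the subtype shift
  itself contributes.  Informative non-driver genes are shifted in the
  *same* direction in both omics so they cannot satisfy the
  negative-correlation rule by construction;
* clinical covariates (age, gender, grade, tumor type, IDH status) with
  mild subtype associations so the covariate tests have signal.

`generate_adversarial_cohort` adds a block of heavy-tailed Student-t
(df 1.5, scale 5) distractor features that dominate the sample variance
after IQR scaling.  PCA spends its 100 components on these distractors
and loses the subtype axis; the autoencoder's squashed inputs compress
the heavy tails, so its latent space keeps the axis.  The contrast is a
designed property of bounded input conditioning, reported as measured.

Not emulated: batch effects, tumor purity, genomic autocorrelation of
methylation, probe-level structure, non-proportional hazards, informative
censoring.  Tests passing on these cohorts show the pipeline recovers the
structure it assumes; they do not certify performance on real data.

## Problem sizes and determinism

The suite and the acceptance script use cohorts of 100–400 samples with
1000 features per omic (300 features for the adversarial contrast), 10
CV splits, 1000 null features for screen calibration and 1000 label
permutations for log-rank calibration — sizes at which every quantity of
interest is statistically stable while the whole suite runs in about a
minute.  One global seed drives cohort generation, weight initialization,
batch shuffling, dropout, K-means restarts, splits and the SVM's internal
calibration; pipeline runs with equal seeds are digest-identical, which
the suite asserts.

## Known limitations

* The C-index ceiling for binary-subtype risk scores discussed above.
* Plain SGD on the summed logistic loss trains slowly at realistic input
  widths; the latent space is useful for screening and clustering long
  before reconstruction is good.
* The Cox screen is univariate by design; correlated latent features are
  screened marginally, so the selected set is not a minimal set.
* The driver rule is the operational two-condition criterion; it does not
  model methylation states (no beta-mixture decomposition), and with
  many genes the per-gene tests are not multiplicity-adjusted (matching
  the stated thresholds).
* Enrichment requires user-supplied GMT collections; no pathway database
  ships with the package.
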