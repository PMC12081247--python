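# Methods

## Model

The pipeline treats a patients × features table X (N × F, real-valued,
modality-tagged columns) as a noisy biclustered matrix and factorizes it as

    X ≈ A S Y,   A ≥ 0 (N × K_s),  S ≥ 0 (K_s × K_f),  Y ≥ 0 (K_f × F),
    AᵀA = I,  YYᵀ = I,

minimising the squared Frobenius reconstruction error. The orthogonality
constraints push A and Y toward scaled indicator matrices, which is what
makes the row-argmax of A a patient clustering and the column-argmax of Y a
feature clustering; S carries scales and cluster–cluster interactions. The
meta-features M = A S are the N × K_f representation passed to the survival
models. Two structural facts follow directly and shape everything
downstream:

* rank(M) ≤ K_s regardless of K_f, so a Cox design built from M is exactly
  rank-deficient whenever K_f > K_s;
* if the hazard depends on the patient cluster only, all survival-relevant
  information in M saturates once the K_s clusters are linearly separable —
  for K_s = 3 that already holds at K_f = 2, so concordance-based selection
  over K_f is legitimately flat.

## Optimization

Alternating multiplicative updates in the square-root-ratio family,
derived from the KKT conditions with the orthogonality constraints folded
into the A and Y updates:

    A  ← A  ∘ √( X YᵀSᵀ / (A AᵀX YᵀSᵀ) )
    Yᵀ ← Yᵀ ∘ √( XᵀA S / (Yᵀ Y XᵀA S) )
    S  ← S  ∘ √( AᵀX Yᵀ / (AᵀA S Y Yᵀ) )

These rules preserve nonnegativity and enforce orthogonality *softly*; the
residuals ‖AᵀA − I‖_F and ‖YYᵀ − I‖_F are reported as diagnostics rather
than driven to zero, because exact nonnegative orthogonal factors are
indicator matrices and unattainable on noisy data. The square-root rules
descend an auxiliary function, not the raw objective, so every sweep is
safeguarded: if the objective would rise beyond a 1e-9 relative tolerance,
the sweep is rolled back and a plain multiplicative sweep (provably
monotone for each factor in turn) is attempted; if that also fails the run
stops at the current iterate. The recorded objective trajectory is
therefore non-increasing by construction, without ever reporting a value
that was not attained.

**Initialization.** Uniform random initialization was tried and rejected:
on noiseless biclustered matrices the optimizer then reaches zero objective
at dense, non-indicator factorizations (the reconstruction error alone does
not identify the block structure once K_f exceeds the signal rank), and
cluster recovery fails. Each restart instead seeds A and Y from k-means
clusterings of the rows and columns of X (normalised indicators, floored at
1e-3 to keep the multiplicative dynamics alive, S = AᵀXYᵀ); restarts differ
through the k-means seeding. The best restart by final objective is kept,
with replacement only on a relative improvement of 1e-6 — at a shared
optimum the final objectives differ by rounding noise and the earliest
restart must win deterministically.

**Canonical component order.** The factorization is invariant to paired
permutations of A's columns / S's rows (and Y's rows / S's columns), so
components are reported in ascending-mass order. Besides reproducibility
this fixes a genuine degeneracy: per-feature min–max rescaling maps a
noiseless lowest-mean patient group to exact zero rows, whose argmax (ties
break to index 0) must land on the massless component rather than collide
with a populated cluster.

**Numerical details.** Denominators carry an epsilon of 1e-12. Default
convergence: relative objective change < 1e-6 or 500 sweeps; 10 restarts.
Input is made nonnegative by per-feature min–max rescaling to [0, 1]
(radiomic features such as skewness are signed, so some affine map is
forced by the constraint set); constant features map to zero and the affine
parameters are available for reporting. Held-out patients are folded in by
nonnegative least squares of each new row against the fixed S Y basis
(`project_patients`), giving fold-honest meta-features a S.

## Feature selection

ICC form is ICC(2,1) — two-way random effects, absolute agreement, single
rater — the standard for inter-observer segmentation-reproducibility, with
a strict > 0.75 keep rule. The estimator is the vectorized two-way ANOVA
closed form, clamped to [−1, 1] (the raw ratio can drop below −1 for two
raters under catastrophic disagreement); tests verify it against a longhand
ANOVA oracle and pingouin's ICC(A,1) to 1e-10. One point the replicate
generator documents explicitly: when rater 2 is rater 1 plus noise of
variance σ², the ANOVA splits that noise over both raters and the expected
ICC is var/(var + σ²/2), not var/(var + σ²); the generator's per-block
noise is calibrated accordingly.

Redundancy pruning is greedy within each modality at its own threshold
(|r| ≥ 0.76 PET, ≥ 0.40 CT, both inclusive): among features currently in a
violating pair, drop the one with the largest mean absolute correlation to
the remaining same-modality features, ties to the later column. The
procedure is idempotent and leaves no surviving within-modality pair at or
above its threshold. Zero-variance columns (Pearson undefined) are dropped
first and logged.

## Survival modelling

* **Cox**: lifelines partial-likelihood maximisation, Efron ties (monthly
  resolution makes ties likely). Because meta-feature designs are exactly
  rank-deficient (rank ≤ K_s), a singular-Hessian failure triggers one
  retry with ridge penalty 1e-3, reported via a warning and in the model
  metadata — never silently.
* **Lasso-Cox**: coordinate-descent L1 path (scikit-survival coxnet,
  30 penalties, alpha_min_ratio 0.01). The penalty is chosen by inner
  event-stratified 3-fold CV on the held-out Breslow partial likelihood
  (Harrell's C optional), applying the one-standard-error rule — the
  sparsest penalty within one SE of the best, the glmnet convention; the
  plain argmax sits on a flat CV profile and under-penalises. Refit on all
  supplied data at the chosen penalty; an all-zero coefficient vector is
  flagged as constant-risk.
* **RSF**: scikit-survival random survival forest, log-rank splitting,
  500 trees, minimum leaf 5, seeded bootstrap; the risk score is the
  aggregated cumulative hazard.

Harrell's C uses the tied-time convention shared by lifelines and
scikit-survival: a pair is comparable when the strictly shorter time
carries an event, or at tied times when exactly one subject has the event
(treated as first); tied risks count 1/2. The test suite pins this to an
exhaustive pair-enumeration oracle.

The protocol runs both evaluation designs: repeated event-stratified
k-fold CV (3 folds × 100 repetitions by default) for the K_f sweep and
model comparison, and a single stratified 7:3 split (154 → 108/46 by
largest-remainder allocation) for held-out tier reporting. Inside the
K_f sweep the factorization is refit on every training fold and held-out
patients are projected by NNLS; factorizing once on all data before CV
leaks the held-out patients' feature structure and is available only as an
explicit opt-in (`refit_per_fold=False`).

## Evaluation endpoints

The ROC endpoint under right censoring is the cumulative/dynamic AUC at a
fixed horizon — default 36 months, near the emulated cohort's mean overall
survival — with inverse-probability-of-censoring weights from the
Kaplan–Meier censoring estimator. Both samples are administratively
censored just past the horizon before weighting: the AUC at the horizon is
unchanged (cases, controls and the censoring estimator on [0, horizon] are
identical) while the weights never need the censoring curve beyond the
training sample's support. A plain binary mode (event by horizon,
censored-before-horizon excluded) is provided for comparison; without
censoring the two coincide exactly. Feature tiers for the AUC analysis are
clinical (age, BMI, ordinal T stage, nodal status), + inflammatory markers
(WBC, NC, LC, PLT, NLR), + meta-features; SUV metrics join via an explicit
flag. Model AUCs are averaged over Cox, Lasso-Cox and RSF.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* **Features**: X = A\*BY\* + ε with indicator A\*/Y\*, Gaussian ε, and a
  block-mean matrix B whose row/column mean gaps equal the configured
  separation exactly (permuted offset construction) plus a double-centred
  jitter of amplitude equal to the separation. The jitter matters: with
  offset-only blocks, per-feature min–max rescaling erases all
  between-feature-block differences and feature clusters become
  unrecoverable by any method; real biclusters differ in profile, not by a
  constant.
* **Survival**: exponential per latent group, rate
  multiplier/baseline (defaults (1, 2, 4)/60 months, i.e. hazard ratio 4
  and group mean survivals 60/30/15 months, overall mean ≈ 35). Chosen for
  closed-form checks (group mean ratios, KM medians ln 2 · scale/mult).
  Censoring is independent Uniform(0, c_max) with c_max solved by Brent's
  method from the closed-form censoring probability of the exponential
  mixture; default target 25%.
* **Raters**: rater 2 = X + per-feature-block Gaussian noise; default
  per-block targets put ICC ≈ 0.9 on all blocks except the last at 0.4,
  emulating one segmentation-sensitive feature family for the filter to
  remove.
* **Clinical covariates**: marginals follow a locally advanced
  cervical-cancer CCRT cohort (age N(54.88, 12.99²) truncated to [18, 90],
  BMI N(22.42, 1.41²); WBC/NC/LC/PLT log-normal with means 7.20/5.16/1.53/
  263.44; SUVmax log-normal mean 15.01; T stage 38/39/23% over T2/T3/T4;
  82% node-positive). NLR = NC/LC holds to machine precision on every row.
  Inflammatory markers, SUV and stage are tilted with the standardized
  log-hazard of the latent group at fixed link strengths (0.35 log-units
  for NC, half that opposing for LC — NLR roughly 3.6× between extreme
  groups, consistent with reported prognostic effect sizes; 0.25 for SUV;
  0.5 for the stage/nodal tilt). These give the intended signal ordering:
  clinical < clinical+inflammatory < +radiomic.
* **Noise level**: default per-feature noise sd equals the block
  separation (2.0). Individual radiomic features are weak measurements;
  the latent groups remain sharply identifiable in aggregate over hundreds
  of features, and pairwise correlations land where the |r| ≥ 0.76 / 0.40
  pruning meaningfully thins the panel (≈ 200 → ≈ 145) instead of
  collapsing it. The sharper recovery fixtures used in tests set
  separation/noise = 4.
* **Determinism**: one integer seed expands into fixed named substreams
  (labels, block means, noise, survival, censoring, clinical, rater 2), so
  adding a component never perturbs the others; regeneration is bit-exact
  and serialized cohorts round-trip exactly (CSV reads use round-trip float
  parsing).

What the generator does **not** emulate: heavy-tailed and discrete feature
distributions, scanner batch effects, within-cluster hazard heterogeneity,
informative censoring, correlated clinical–radiomic measurement noise, and
real radiomic redundancy geometry. Passing tests therefore demonstrate
correctness of the machinery and the qualitative orderings under the
assumed structure, not clinical performance.

An important ceiling follows from the design: when hazards depend only on
the latent group with multipliers (1, 2, 4), the *oracle* risk score has
C ≈ 0.64 (between-group concordance λ_j/(λ_i+λ_j), within-group pairs tied
at 1/2). Tests accordingly compare models to the same-cohort oracle and to
each other, not to absolute C-index levels that the generative law cannot
support.

## Driver problem sizes

The end-to-end comparison driver defaults to the emulated cohort scale
(154 patients, 200 features) with desk-scale computation: K_f grid 2…10,
2 CV repetitions inside the sweep, 150-tree forests in the sweep arm,
10 repetitions for the clinical models, and 2-restart / 200-sweep
factorizations. Function-level defaults retain the full protocol (3 × 100
CV, 500-tree forests, 10 restarts); the driver's reduced settings are a
deliberate default for a complete run in about a minute, and every knob is
a config field.

## Known limitations

* Orthogonality is soft; on low-SNR data A can drift dense and the argmax
  clustering degrades before the reconstruction error does. The residual
  diagnostics surface this.
* The greedy redundancy pruning is order-dependent by design (documented
  tie-breaks), not a global maximum-subset search.
* The Lasso path inherits coxnet's alpha grid; a penalty exactly 0 is
  approximated at 1e-9 with tightened tolerances.
* Pairwise log-rank p-values are unadjusted by default (Bonferroni is a
  flag), matching common reporting practice for three-group comparisons.
* The 2-group and 3-group stratifications come from independent refits at
  the respective K_s, not from merging the 3-group solution.
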