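# coclustsurv

Two-way co-clustering of radiomic feature tables with censored survival
prediction.

## The problem

Radiomic studies of solid tumours routinely extract a thousand or more
quantitative features (shape, first-order intensity, texture, wavelet
variants) from PET/CT segmentations of cohorts of only one or two hundred
patients. Supervised feature selection at that dimensionality overfits;
plain unsupervised reduction (PCA) ignores the group structure that makes
features prognostic. `coclustsurv` implements a pipeline for this setting,
aimed at statisticians and imaging researchers building overall-survival
models from extracted feature tables:

1. **Reproducibility filtering** — features measured by two independent
   raters are kept only if ICC(2,1) > 0.75; survivors are pruned for
   within-modality Pearson redundancy (|r| ≥ 0.76 PET, ≥ 0.40 CT).
2. **Two-way clustering** — the core method, an orthogonality-constrained
   nonnegative matrix tri-factorization that simultaneously sub-clusters
   patients and features:

   ```
   min_{A,S,Y} ‖X − A S Y‖²_F
   s.t.  A ≥ 0, S ≥ 0, Y ≥ 0,  AᵀA = I,  YYᵀ = I
   ```

   with X ∈ ℝ^{N×F} the rescaled feature matrix, A ∈ ℝ₊^{N×K_s} the patient
   sub-cluster memberships, Y ∈ ℝ₊^{K_f×F} the feature sub-cluster
   memberships and S ∈ ℝ₊^{K_s×K_f} their coupling. The meta-features
   **M = A S** (N × K_f) are the model inputs; the row-wise argmax of A
   stratifies patients into risk groups.
3. **Stratification** — Kaplan–Meier curves per cluster, overall and
   pairwise log-rank tests at K_s = 2 and 3.
4. **Prediction** — Cox proportional hazards, Lasso-penalised Cox (penalty
   by nested 3-fold CV) and random survival forests (500 trees, minimum
   leaf 5), compared by Harrell's C under repeated event-stratified 3-fold
   cross-validation, with a K_f sweep over 2…10, PCA / K-means / clinical
   baselines, and cumulative/dynamic IPCW AUC for nested feature tiers
   (clinical → +inflammatory markers → +meta-features).

Because no clinical cohort ships with the package, a first-class synthetic
cohort generator produces ground-truth data with the same statistical
structure — biclustered features, two-rater replicates with controlled ICC,
clinical covariates with NLR = NC/LC, and cluster-linked exponential
survival — so every stage is validated against known truth.

## Worked example

`examples/predict_survival.py` builds a 154-patient synthetic cohort,
selects features, extracts nine meta-features at K_s = 3, and cross-validates
the three models:

```
meta-features: 9 columns from 146 selected features
      cox: C-index 0.631 +- 0.041 (10 x 3-fold CV)
cox_lasso: C-index 0.586 +- 0.055 (10 x 3-fold CV)
      rsf: C-index 0.589 +- 0.030 (10 x 3-fold CV)
oracle C-index with the true group hazards: 0.626
```

The oracle line scores the *true* latent hazards: with survival driven by
three groups at hazard ratio 4, no risk score can rank pairs much better
than ≈ 0.63, so the Cox model on meta-features has extracted essentially
all of the available prognostic signal. The other examples
(`simulate_cohort.py`, `select_features.py`, `two_way_clustering.py`,
`stratify_risk_groups.py`, `compare_methods.py`) each walk one capability
the same way.

A thin CLI mirrors the library:

```bash
coclustsurv simulate --out cohort/ --seed 1
coclustsurv select --features cohort/features.csv \
    --features-rater2 cohort/features_rater2.csv --out selected/
coclustsurv factorize --features cohort/features.csv --ks 3 --kf 9 --out factors/
coclustsurv evaluate --out report/ --seed 1
```

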