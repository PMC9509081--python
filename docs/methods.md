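# Methods

This note documents the models and procedures implemented in `pclike`, the
parameter choices that matter, what the synthetic-cohort generator does and
does not emulate, and the numerical conventions.

## Statistical model of the classifier

**Scale.** CTC level and bone-marrow plasmacytosis are fractions in [0, 1]
analyzed on the log-odds scale. `logit(p, eps)` clamps `p` into
`[eps, 1−eps]` before the transform; the default `eps = 1e−6` sits below the
flow-cytometric limit of detection (~1e−5), so "undetectable" maps to a
finite, extreme log-odds value rather than −∞. Samples with undetectable CTC
are excluded from association fitting by default (the association is defined
over measured CTC levels); an option imputes half the detection limit
instead.

**Gene ranking.** Per gene, OLS of log expression on intercept, logit CTC,
and logit burden. The CTC coefficient (the "logFC" per log-odds CTC unit)
carries a two-sided t-test on n−3 degrees of freedom. No moderated-variance
(limma-style) shrinkage is applied — with ~100 samples the per-gene variance
estimates are stable and plain OLS keeps the estimator transparent. The fits
are vectorized (one shared projection matrix across genes), which is what
makes per-fold re-ranking inside leave-one-out cross-validation affordable;
unit tests pin the vectorized path to per-gene statsmodels fits at 1e−8.
Multiple testing uses textbook Benjamini-Hochberg step-up (cross-checked
against statsmodels). Ranking order is ascending p, ties broken by
descending |β|, then gene id, so gene selection is deterministic.

**Score.** Equal-weight signed mean of training-standardized expression,
`(1/k)·Σ sign(β_g)·z_g`. The published score's exact per-gene coefficients
are not available, so equal weights with data-driven signs are the default;
the serialized model schema carries real per-gene weights so externally
estimated coefficients can be substituted without code change. Signed means
of z-scores are affine-invariant: any per-gene affine re-measurement
(platform change) followed by re-estimated standardization reproduces the
scores exactly, which the suite asserts at 1e−12.

**Gene-count selection.** LOOCV with re-ranking inside every fold: the
held-out sample never influences the fold's gene ranking, signs, or
standardization (a permutation test in the suite confirms fold rankings
ignore disease labels entirely, since ranking uses only CTC and burden). The
per-k criterion is ROC AUC of held-out scores for pPCL vs NDMM; the smallest
k attaining the maximum wins, favoring parsimony under ties. A fast mode
(`rerank_per_fold=False`) ranks once and cross-validates only the
standardization and score; it is cheaper and slightly optimistic.

**Threshold.** The decision cutoff is the minimal PCL-like score among
discovery pPCL samples, making discovery pPCL sensitivity 100% by
construction; the comparison is inclusive (≥). The minimum is taken over
both in-sample scores and the leave-one-out (out-of-fold) scores of the same
pPCL samples. The in-sample minimum alone is biased upward: gene selection
favors genes whose residual noise aligns with the high-leverage pPCL
samples, so their in-sample scores — and hence a min-score threshold — carry
selection optimism that costs sensitivity on new cohorts. The out-of-fold
scores are free of that optimism; taking the minimum over both preserves the
100%-by-construction guarantee while protecting external sensitivity. Even
so, a min-of-m calibration misses roughly 1/(m+1) of new true positives by
order statistics alone (m = number of discovery pPCL samples), which is
worth knowing when reading sensitivity numbers.

## The synthetic-cohort generator

`SimulationConfig`/`generate_cohort` produce the study conditions the
pipeline assumes:

- **Latent PCL-likeness factor L** drives both CTC level and signal-gene
  expression. L is a two-component mixture: background `Normal(0, 2.0)` and,
  with probability `ppcl_frac = 0.22`, a PCL-like subpopulation
  `Normal(7.5, 1.5)` — emulating a discovery cohort into which clinically
  leukemic patients were deliberately enrolled alongside NDMM. Mixture
  membership is the ground-truth PCL-like flag.
- **CTC model**: `logit(CTC) = −7.0 + L + 1.5·logit(b) + Normal(0, 0.5)`,
  with burden `b ~ Beta(2, 4)` (median ≈ 0.31, typical NDMM plasmacytosis).
  These values were set so the generator reproduces the summary statistics
  the analysis setting reports: a weak positive burden→CTC association
  (adjusted R² ≈ 0.13–0.15), background exceedance of the 20% clinical
  cutoff near 2%, overall pPCL label rate ≈ 13% of a discovery cohort
  (~15 of 110), NDMM median CTC of a few hundredths of a percent, and
  ~10% of samples below the detection limit.
- **Genes**: `n_signal_genes = 100` respond to L with slope
  `signal_effect = 0.5` log-expression units per log-odds unit;
  `n_confounded_genes = 100` respond to logit burden only (slope 0.5); the
  remaining genes are noise; all genes carry `Normal(0, 1)` residual noise
  and per-gene baselines shared across cohorts via a dedicated
  `gene_param_seed` (a discovery/validation pair measured with one pipeline
  shares its gene panel — without this, standardization statistics would not
  transfer across cohorts and no classifier could validate).
- **Labels**: pPCL iff CTC ≥ 20% (the clinical rule), checkable per sample.
  Note the label is a noisy function of L: a small fraction of labeled pPCL
  are background samples that crossed the line through burden/noise; no
  transcriptomic classifier can detect those, which caps attainable
  sensitivity (~2–3% here).
- **Survival**: exponential event times with log-hazard
  `log(hr)·1[PCL-like]` per endpoint (defaults hr 1.85 for PFS, 2.12 for
  OS, baseline medians 30/60 months) and independent uniform censoring whose
  horizon is solved numerically from the target censoring fraction (0.3).
  Exponential hazards with independent censoring are the simplest model
  under which a Cox fit recovers the true hazard ratio.
- **Platform distortion**: per-gene `a_g + c_g·x + noise`, with
  `a_g ~ Normal(0, 0.5)`, `c_g ~ LogNormal(0, 0.2)` (hence positive), and
  optional measurement noise — a paired re-measurement of the same samples
  on a second protocol.
- **Determinism**: one master seed; expression, survival, and platform
  stages use fixed documented offsets; multi-study generation derives study
  i's seed as `seed + 1000·(i+1)` with disjoint sample-id prefixes.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: count distributions (no negative-binomial
layer; values are Gaussian on the log scale), gene–gene correlation beyond
the single latent factor and the burden block, batch structure within a
platform, informative censoring, competing risks, and any relationship
between the synthetic gene indices and real gene identities.

## Evaluation and survival conventions

- **CTC prediction**: OLS of observed logit CTC on score + logit burden;
  variance shares by sequential (Type-I) sums of squares with the score
  entered first (configurable). The split is order-dependent for correlated
  predictors; the suite checks the *total* explained variance is
  order-invariant. Shares sum to 1 within 1e−9 by construction.
- **Group comparisons**: two-sided Wilcoxon signed-rank (paired) or rank-sum
  (unpaired), exact for ≤ 25 observations without ties, normal approximation
  with tie/continuity correction otherwise; the method used is reported.
- **Fisher's exact test**: two-sided p by the minimum-likelihood convention
  (sum of conditional hypergeometric probabilities ≤ observed). The reported
  odds ratio is the sample ratio ad/bc; 0.5 is added to every cell for
  display only when a zero cell makes it degenerate, and that correction is
  flagged. The scaled odds ratio for co-occurrence displays is the logistic
  sigmoid of the log odds ratio (0.5 at OR = 1).
- **Co-occurrence**: all unordered feature pairs on pairwise-complete
  samples, BH across pairs, significant cells returned; single-level
  features after missing-data removal are skipped and reported.
- **Survival**: Kaplan-Meier and k-group log-rank via lifelines; composite
  groups join factor levels with `" / "`. Cox models delegate to lifelines'
  `CoxPHFitter` with study-stratified baseline hazards, Breslow tie
  handling, and Wald confidence intervals (Efron weighting would differ
  slightly on heavily tied data). PFS events are progression or death from
  any cause; OS events are death from any cause.
- **Meta-analysis**: DerSimonian-Laird — Cochran's Q with fixed-effect
  weights `w = 1/se²`, `tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, pooled
  estimate with weights `1/(se² + tau²)` and a normal-approximation 95% CI.
  With k = 1 or homogeneous inputs it reduces exactly to the fixed-effect
  answer.

## Numerical choices and degenerate inputs

- Zero-variance genes get sd = 1 with a warning record rather than an error,
  so a constant probe cannot poison standardization.
- Collinear or constant design columns in the association and CTC-prediction
  fits raise errors naming the degenerate column.
- LOOCV folds with degenerate designs are skipped and counted; more than 10%
  skipped is an error. Classes must both be present.
- A gene with exactly zero residual variance and zero slope reports p = 1.
- Model scoring requires ≥ 50% of model genes (configurable); below that a
  coverage error is raised rather than returning a score on a sliver of the
  panel.
- Expression TSV round-trips exactly: writes use 17 significant digits and
  reads use round-trip float parsing.

## Problem sizes used in the test suite

The suite exercises the pipeline at the discovery scale it models (110
samples × 2,000 genes, 20 replicate seeds; validation cohorts of 300;
survival simulations of 8 × 250 and 4 × 500 with expression generation
reduced to a handful of genes, since survival analyses do not consume the
expression matrix). These sizes keep a full run in a few minutes while
leaving the per-replicate statistics at the scale the procedures assume.

## Known limitations

- The packaged 54-gene model is a synthetic stand-in for the published gene
  table (identities are not machine-readably available here); it validates
  the fixture pathway and the threshold rule, not real-data gene identities.
- Equal-weight scores are a design choice where the published combination
  rule is underdetermined; per-gene weights can be supplied via the model
  JSON.
- Sequential ANOVA shares depend on term order for correlated predictors;
  only the order used is reported.
- The min-score threshold rule ties external sensitivity to the size and
  composition of the discovery pPCL set (see the order-statistics remark
  above); cohorts with few enrolled pPCL will calibrate noisy thresholds.
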