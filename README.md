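# pclike

Transcriptomic classification of **plasma cell leukemia-like (PCL-like)
multiple myeloma** from bulk tumor expression profiles, with a synthetic
cohort simulator so the whole pipeline can be exercised and tested without
patient data.

## The scientific problem

Primary plasma cell leukemia (pPCL) is the most aggressive presentation of
multiple myeloma, diagnosed clinically when circulating tumor cells (CTCs)
reach ≥ 20% of peripheral-blood cells. Some newly diagnosed myeloma (NDMM)
patients never cross that clinical line yet carry bone-marrow tumors whose
transcriptome looks like pPCL — and their prognosis is correspondingly poor.
This package implements the construction, calibration, application, and
prognostic evaluation of a transcriptomic classifier for that PCL-like state,
for computational biologists who want to build such a score on their own
cohorts or apply a packaged gene set to new expression data.

## The method

Throughout, fractions (CTC level *p*, bone-marrow plasmacytosis *b*) are
modeled on the log-odds scale, `logit(p) = ln(p/(1−p))`, with an ε-clamp so
undetectable CTC maps to a finite extreme value.

1. **Gene ranking with covariate adjustment.** For each gene *g*, ordinary
   least squares of log expression on `1 + logit(CTC) + logit(burden)`:

   `x_g = α_g + β_g·logit(CTC) + γ_g·logit(b) + ε`

   β_g is the expression change per log-odds CTC unit *independent of tumor
   burden*; genes are ranked by the two-sided t-test p-value of β_g with
   Benjamini-Hochberg FDR control across all genes.
2. **Gene-count selection by LOOCV.** For each left-out sample, genes are
   re-ranked on the remaining samples and top-*k* models are scored on the
   held-out sample for each candidate *k*; the selected *k\** is the smallest
   *k* maximizing the held-out ROC AUC for pPCL vs NDMM.
3. **Score and threshold.** The PCL-like score of a sample is the
   equal-weight signed mean of its training-standardized expression over the
   model genes, `score = (1/k)·Σ_g s_g·z_g` with `s_g = sign(β_g)`. The
   decision threshold is the minimal score among discovery pPCL samples
   (taken over in-sample and leave-one-out scores), and the rule is
   inclusive: `score ≥ threshold ⇒ PCL-like`.

Evaluation utilities cover prediction of CTC level from score + burden with a
sequential (Type-I) ANOVA variance decomposition, Wilcoxon group comparisons,
Fisher's-exact co-occurrence matrices with sigmoid-scaled odds ratios,
Kaplan-Meier/log-rank analysis, study-stratified Cox models (via lifelines),
and DerSimonian-Laird random-effects meta-analysis of per-study hazard
ratios.

A packaged 54-gene model with threshold 3.55 ships with the library
(`load_packaged_model()`). Its gene identities are a **synthetic stand-in**
(see the fixture's metadata); scoring with it requires standardization
statistics from a user-declared reference cohort.

## Worked example

```python
from pclike import (SimulationConfig, generate_cohort, build_classifier,
                    score_samples)

discovery = generate_cohort(SimulationConfig(seed=1))
model = build_classifier(discovery.expression, discovery.annotation)
print(model.n_genes, round(model.threshold, 3))
# 100 0.382

validation = generate_cohort(SimulationConfig(seed=10001, n_samples=300),
                             study_id="V")
scored = score_samples(model, validation.expression)
ppcl = (validation.annotation["disease_label"] == "pPCL").to_numpy()
print(f"validation pPCL sensitivity: "
      f"{(scored.loc[ppcl, 'call'] == 'PCL-like').mean():.0%}")
# validation pPCL sensitivity: 100%
```

The built model here selected 100 genes with a calibrated threshold of 0.382
(score units are cohort-standardized, so the numeric threshold differs from
the packaged model's 3.55); every clinically leukemic sample in the
independent validation cohort scored at or above it.

The same pipeline is available from the shell:

```bash
pclike generate --out cohort/ --seed 1
pclike rank  --expr cohort/expression.tsv --annot cohort/annotation.csv --fdr 0.05 --out ranked.csv
pclike build --expr cohort/expression.tsv --annot cohort/annotation.csv --grid 10,25,54,100 --out model.json
pclike score --model model.json --expr cohort/expression.tsv --out scores.csv
```

There is also a scikit-learn style estimator (`PclLikeClassifier`) with
`fit` / `decision_function` / `predict` for use inside sklearn tooling.

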