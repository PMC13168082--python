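# Methods

This note documents the models, procedures, parameter choices, and known
limitations of the `sexpanel` pipeline in the package's own terms.

## Problem setting

Bladder cancer is strongly sex-dimorphic: it arises far more often in males
but tends to progress more aggressively in females. The pipeline searches
for sex-related diagnostic gene panels in bulk RNA-seq by treating biomarker
discovery as a feature-selection problem over three classification tasks:

1. **male_dev** — tumor vs non-tumor within male samples;
2. **female_dev** — tumor vs non-tumor within female samples;
3. **tumor_sex** — male vs female within tumor samples.

Because public cohorts contain very few non-tumor bladder samples, the two
development tasks train on a multi-batch cohort (a tumor-heavy cohort, a
non-tumor-only cohort, and a small mixed cohort) merged after per-dataset
normalization; the progression task uses a single tumor-rich cohort.

## Synthetic cohorts

The generator (`sexpanel.sim`) is first-class, tested code: it defines the
ground truth every downstream stage is checked against.

**Count model.** Gene g in sample j is drawn NB(mu_gj, alpha) with
`var = mu + alpha * mu^2`, via the gamma–Poisson mixture. The mean factorises
as

```
mu_gj = exp(b_g) * exp(e_g,batch(j)) * L_j * 2^{c_g,cell(j)}
```

where `b_g ~ N(3.5, 1.5^2)` (natural log) sets the baseline, `e_g,b ~
N(0, 0.4^2)` is a gene-specific multiplicative batch effect shared by all
samples of a batch, `L_j ~ logN(0, 0.3^2)` is library-size variation, and
`c` is the planted condition effect of the sample's (sex, status) cell.
Dispersion defaults to `alpha = 0.1`, a typical bulk RNA-seq value. Gene
lengths are uniform on [200, 10000] bases and fixed per gene so TPM length
correction is genuinely exercised.

**Planted classes.** Five disjoint classes with known log2 fold changes
(alternating up/down, default |lfc| = 2):

* *male_specific* / *female_specific* — tumor effect in one sex only;
* *shared_same* — identical tumor effect in both sexes (the class the
  exclusion rule must remove from sex-specific pools);
* *shared_opposite* — tumor effect with opposite sign per sex (deliberately
  retained by the exclusion rule);
* *sex_dimorphic* — a male-tumor vs female-tumor difference, realised as a
  symmetric ±lfc/2 split between the two tumor strata. Its default
  magnitude is 1.6 so the per-sex half effect (0.8) sits below the
  |log2FC| > 1 DEG threshold and the class does not leak into the
  development pools; the tumor_sex contrast still sees the full 1.6.

Because the classes are physically entangled (a male-specific tumor gene
really does differ between male and female tumors), "contamination" of a
task's DEG pool is always measured against the genes with *no true effect in
that task's contrast*, not against class labels alone.

**Default cohort.** Three training batches and two external batches whose
(sex × status) cell sizes mirror the published class-distribution table at
roughly one-fifth to one-half scale, preserving the characteristic female
scarcity (e.g. 60 male vs 20 female tumors in the main training batch, and a
4-sample female tumor stratum in the small mixed batch). The batch-effect
magnitude between real cohorts is unknown; sigma = 0.4 was chosen once as
enough to make uncorrected batches almost perfectly separable by a linear
classifier, as observed in real multi-cohort merges.

**What the generator does not emulate:** isoform structure, read-level
noise, GC/length biases beyond the fixed length factor, correlated gene
modules, mutation or copy-number signal. Passing tests therefore demonstrate
that the pipeline recovers planted *mean-shift* signal under NB noise,
imbalance, and batch structure — not that it would recover any particular
real biomarker.

## Normalization and merging

`counts -> collapse duplicates -> TPM -> log2(x+1) -> per-dataset z-score ->
merge on common genes`, with the stage enforced by a label on every matrix.
Duplicate gene IDs are summed on raw counts (training sets) and averaged on
the TPM scale (external sets, which arrive as TPM in the real-data setting).
z-scoring uses the sample standard deviation (n−1 denominator; the
convention is fixed here because different implementations disagree).
Zero-variance genes become all-zero rather than being dropped, keeping gene
sets aligned across batches. External test sets are always z-scored with
their own per-dataset statistics — training statistics cannot be applied
because the training matrix is itself a concatenation of independently
scaled datasets.

## Differential expression

Per gene, counts follow an NB log-linear model with a log size-factor
offset, an intercept, batch indicators, and the condition indicator. Size
factors use median-of-ratios over all-positive genes (with a
positive-counts-only fallback when no gene qualifies). Fitting is IRLS with
weights `mu / (1 + alpha*mu)`, vectorised across genes (batched p×p solves);
the linear predictor is clipped at ±30 so separated genes (a group with all
zeros) saturate instead of diverging. Dispersion is a Pearson-residual
moment estimate `sum((y-mu)^2 - mu)/mu^2 / (n - p)` with floor 1e-8 and
ceiling 20, refined once by refitting. The condition coefficient's Wald
statistic gives a two-sided normal p-value; BH adjustment runs across tested
genes; all-zero genes are excluded and reported.

This is deliberately *not* a numerical clone of DESeq2: dispersion
shrinkage, independent filtering, and outlier replacement are omitted. The
contract is calibrated type-I error — on a 2,000-gene null simulation the
raw p < 0.05 fraction sits in [0.035, 0.065] — and the test suite
additionally cross-checks fold changes and p-values against pydeseq2 on a
small fixture (median |Δlog2FC| < 0.05, p-value rank correlation > 0.95).

**DEG filtering and exclusion.** DEGs require padj < 0.05 *and*
|log2FC| > 1.0, strict inequalities. The male pool removes genes that are
DEGs in the female contrast with the same direction (and vice versa); the
tumor_sex pool removes genes that are male-vs-female DEGs in non-tumor
tissue with the same direction. Oppositely regulated genes are retained in
both cases. The non-tumor contrast runs once, outside the fold scheme; all
other contrasts run per fold on the four training folds, so the DEG universe
legitimately differs between folds.

## Cross-validation and feature selection

Samples are split into five stratified folds. The fold builder processes
classes largest-first, shuffles each class under the seed, and deals members
to the currently smallest fold: per-fold class counts stay within one of the
proportional share, and classes smaller than k (a real feature of these
cohorts — one training batch has four female tumors) are spread across folds
rather than rejected.

All hyperparameter searches maximise the composite metric

```
0.5 * F1 + 0.3 * AUROC + 0.2 * balanced accuracy
```

on inner stratified folds drawn from the training folds only. F1 carries
the largest weight for its sensitivity to the true-positive rate under class
imbalance. On a degenerate single-class inner validation fold the AUROC term
falls back to 0.5 (no ranking information). Search order is deterministic
and ties go to the first-encountered candidate.

The four selectors produce a top-300 panel per fold:

* **opt_rf** — grid-tuned random forest grown `rf_iterations` times (default
  1,000; reduced in desk-scale runs) with consecutive seeds; each forest
  adds the importances of its own top 300 genes to a running sum.
* **svm_rfe** — linear SVM RFE removing `max(1, round(0.001 * current))`
  features per iteration until 300 remain (the floor guarantees
  termination; 1,000 starting features take exactly 700 iterations).
  Survivors are ranked by the final |coefficient|.
* **logreg_l1** — L1-penalised logistic regression at the tuned strength on
  standardised data, ranked by |coefficient|. Any convergent optimizer for
  the penalized loss is acceptable; liblinear is used here.
* **dgea_p** — genes with |log2FC| > 1 ordered by adjusted p-value (padj
  ties break by |log2FC| descending, then gene id).

Standardisation for the linear models is fitted inside each inner training
fold (via pipelines) during tuning, and on the selector's own training data
for the final fit — validation folds never contribute scaling statistics.
The published description leaves the search grids unspecified; the modest
fixed spaces in `sexpanel.config` are recorded in the run manifest.

## Rank aggregation

The 5 × 4 = 20 rankings of a task are combined by robust rank aggregation:
each gene's ranks are normalised by the universe size N (the union of the
per-fold DEG pools), genes absent from a list receive the worst-case
normalised rank 1 (the standard partial-list treatment, which keeps rho
conservative), and

```
rho(g) = min_k P( Beta(k, n-k+1) <= r_(k) )
```

with Bonferroni correction `min(1, N * rho)`. The same operation aggregates
each method's five fold rankings into a cross-fold consensus, and consensus
overlaps are tabulated as exact Venn regions (2–4 panels). Whether the
source analysis aggregated the 20 lists in one pass or stratified by method
first is ambiguous in its description; equal-weight single-pass aggregation
is implemented, which is the plain reading of "all rankings within a task
were combined".

## Evaluation

Four model families — random forest, linear-kernel SVM, KNN, and
gradient-boosted trees (XGBoost) — are tuned on the full training data by
inner CV composite (exhaustive search for SVM/KNN, randomised search for the
tree ensembles; a Bayesian search arm is not provided), refitted, and scored
on each external cohort, restricted to the panel under test and its top-N
prefixes (default ladder 300…10). Panel genes missing from a cohort are
dropped with a warning, mirroring the intersect-on-common-genes behaviour
elsewhere. The positive class is tumor (or male for tumor_sex); hard labels
use the 0.5 probability threshold. Each metric carries a 95% percentile
bootstrap CI over 500 resamples of the test samples; resamples lacking both
classes are skipped for class-dependent metrics and counted in the report.
Internal validation scores each per-fold panel only on its own held-out fold
and averages over folds; aggregated panels are rejected there because they
were assembled outside the cross-validation scheme.

## Numerical and design choices

* Tie-breaking everywhere: score desc → |effect| desc → gene id asc.
* Stage seeds are split deterministically from one master seed
  (`numpy.random.SeedSequence.spawn`); reruns with the same configuration
  reproduce panel files byte-identically.
* The tumor_sex training cohort is the single tumor-rich batch on the
  log2(TPM+1) scale (no z-scoring — there is nothing to merge); its
  non-tumor exclusion contrast pools all non-tumor training samples with a
  batch covariate.
* Desk-scale problem sizes used by the tests and analysis scripts: 2,000
  genes, the default cohort above, 20 optimized-RF iterations, reduced
  search grids, rf-only evaluation. These are configuration values, chosen
  so the full pipeline runs end to end in minutes; the selectors, tests and
  thresholds are identical to the full-scale configuration.

## Limitations

* The NB Wald test can be slightly anticonservative at very small sample
  sizes (moment dispersion, no shrinkage); calibration is verified at the
  cohort sizes used here (tens of samples per group).
* Independent per-dataset z-scoring removes location/scale batch structure
  only; correlated batch effects would survive it. This is a property of
  the method being studied, not an implementation artefact.
* With a handful of samples in rare strata (female non-tumor in the small
  batches), bootstrap intervals for the female task are wide and can
  degenerate — the same behaviour the real cohorts show.
* Panel evaluation assumes external cohorts share the training label
  definitions; no covariate shift correction is attempted.
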