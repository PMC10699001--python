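# Methods

This note documents the statistical machinery in `m6atlas`, the defaults we
chose where the method class leaves a decision open, and the limits of what
the synthetic cohort can demonstrate.

## Regulator catalog and signature registry

The subtyping substrate is the standard 24-gene m6A panel: 8 writers
(METTL3, METTL14, WTAP, ZC3H13, VIRMA, CBLL1, RBM15, RBM15B), 2 erasers
(FTO, ALKBH5) and 14 readers (YTHDC1/2, YTHDF1/2/3, IGF2BP1/2/3,
HNRNPA2B1, HNRNPC, RBMX, LRPPRC, ELAVL1, FMR1). We use the canonical HGNC
symbol LRPPRC throughout. Gene identifiers are matched case-insensitively
and stored upper-case; the package accepts symbol-indexed matrices directly
and does no Ensembl mapping.

The signature registry carries the 11 Mariathasan immune/oncogenic process
categories (antigen processing machinery, CD8 T-effector, immune
checkpoint, nucleotide-excision repair, mismatch repair, DNA replication,
DNA damage repair, EMT markers, Wnt targets, pan-fibroblast TGF-β response,
angiogenesis) plus fibroblast/Treg immune-suppression panels used for
group comparisons. The CD8-effector (8 genes) and checkpoint (7 genes)
panels follow the published lists verbatim; the remaining panels are
curated representative members of the published sets, and users can replace
any of them with a GMT file.

## Mixture-model subtyping

`mixture.fit_gmm` is a standard EM for Gaussian mixtures over six
covariance families — spherical/diagonal/full crossed with
equal/varying across components (parameter counts 1, K, d, Kd, d(d+1)/2,
Kd(d+1)/2). Model selection maximizes `BIC = 2 log L − p log n` over
K ∈ 1..K_max and all families, the convention in which *larger* is better.

Numerical choices: k-means++ seeding with `n_init` restarts (best final
log-likelihood kept); convergence at relative log-likelihood change
≤ 1e-6; at most 500 iterations; a variance floor of 1e-6 on eigenvalues /
diagonal entries guards against collapse onto single points. Cluster labels
are renumbered 1..K by decreasing size (ties by original component index)
so outputs are stable across runs; any fixed convention would do. Candidate
K ≥ n is skipped and noted in the BIC table; a grid where every fit
degenerates raises with the table attached.

Regulator expression is z-scaled per gene before clustering by default
(`scale: false` turns this off); the choice is echoed into the run report.

## Moderated differential expression

For each cluster k the contrast is k vs all other samples pooled. Per gene,
a two-group linear model gives the pooled residual variance `s²_g` with
`d_g = n − 2` degrees of freedom and the contrast `log2FC = mean_k −
mean_rest` (expression is already log₂(FPKM+1); DE on this scale is the
default — the raw-FPKM reading is available via the `de_scale` option but
is not recommended, since the moderated-t working assumption of
approximate normality holds on the log scale).

The empirical-Bayes prior (d₀, s₀²) is estimated by moment matching on
`log s²_g` (digamma/trigamma equations; the trigamma inverse is solved by
Newton iteration), zero-variance genes excluded from estimation, floored at
1e-8 and flagged rather than dropped. The moderated t uses
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` with `d₀ + d_g` degrees of freedom
(normal reference when d₀ = ∞). The implementation reproduces the
reference R implementation (limma) to ~1e-14 on shared inputs, and the test
suite verifies both that equivalence and a from-the-formulas brute-force
oracle at 1e-8.

DEG calls use adjusted p < α (strict) and |log₂FC| ≥ 1 (two-fold) by
default, with the 0.5 cut also reported because both thresholds appear in
practice. Multiple testing is Benjamini–Hochberg within each contrast.
"Overlap DEGs" are the intersection of the K one-vs-rest DEG sets — the
strictest reading — with `min_contrasts` available to relax to "called in
at least k contrasts". Over-representation of DEGs in gene sets is the
upper-tail hypergeometric test with BH across sets; this stands in for
heavier enrichment machinery because the pipeline only uses enrichment
comparatively.

## The m6A score

Signature genes are the overlap DEGs that also pass a univariate Cox screen
at Wald p < 0.05 (strict), sorted lexicographically for determinism. PCA
runs on the centered (optionally unit-scaled) signature expression; the
score is the sum of each sample's PC1 and PC2 projections, the
Genomic-Grade-Index-style construction. Unscaled PCA is the default so
that expression magnitude keeps its weight.

Eigenvector signs are fixed by orienting each loading's
largest-|weight| entry positive. This makes outputs reproducible but the
biological direction of the score (whether high is adverse) is a
convention, not an estimate — the orientation metadata travels with the
result, and downstream tests use |ρ| or planted-truth sign where direction
matters. Score groups come from 1-D mixture clustering of the scores
(spherical families, K ≤ 6), labelled by ascending group mean.

## Survival machinery

All survival estimation is implemented in the package and cross-checked in
tests against lifelines / scikit-survival:

* **Cox PH** — Newton–Raphson on the partial likelihood with step-halving;
  Efron tie correction by default (Breslow by flag). Risk-set sums come
  from suffix cumulative sums over the time-sorted cohort, so one
  evaluation is O(n p²); the untied case is fully vectorized. Convergence
  is a gradient norm below `tol` relative to the likelihood scale;
  monotone-likelihood (separation) fits are capped at |β| ≤ 20 and flagged
  unconverged rather than raised. Standard errors come from the observed
  information.
* **Kaplan–Meier / log-rank** — product-limit estimates and the K-group
  observed-minus-expected statistic with the hypergeometric variance,
  df = K − 1.
* **Lasso-Cox** — coordinate descent on the IRLS-linearized penalized
  partial likelihood (Breslow ties, diagonal Hessian weights), genes
  standardized internally and coefficients returned on the original scale.
  The λ path has 100 log-spaced points from λ_max (the smallest penalty
  with an all-zero solution, from the KKT condition at β = 0) down to
  0.05·λ_max, warm-started. Cross-validation is k-fold (seeded, stratified
  by event status) on the V&VH partial-likelihood deviance
  `−2[ℓ(β₋ₖ; all) − ℓ(β₋ₖ; train)]`; the selected λ is the CV minimum, not
  the 1-SE rule, because determinism and a single defensible default
  mattered more than parsimony. At λ = 0 the solver runs to Newton
  accuracy and matches the unpenalized fit.
* **Risk model** — linear predictor over the selected active set; High/Low
  groups split at the median score (invariant to monotone shifts of the
  score). Time-dependent AUC is the IPCW cumulative/dynamic estimator with
  Kaplan–Meier censoring weights 1/G(t⁻) for cases; it matches
  scikit-survival's estimator exactly and errors for horizons beyond the
  last follow-up.

Kruskal–Wallis, χ² (no continuity correction) and Spearman wrap scipy; the
all-tied Kruskal–Wallis case returns H = 0, p = 1 by contract instead of
propagating scipy's error.

## Copy-number, mutation and immune metrics

Fraction genome altered is the covered-length fraction with
|log₂ ratio| > 0.2 (strict exceedance; the cBioPortal convention, and
configurable because the quantity has no single canonical definition). The
aneuploidy score is an arm-level count: an arm is altered when ≥ 50% of its
covered length exceeds the same threshold; both parameters are exposed, and
the score is recomputed from SEG rather than taken from any published
per-sample table. TMB divides qualifying mutations by a 38 Mb exome, with
the usual nonsynonymous classes (missense, nonsense, nonstop, frameshift
and in-frame indels, splice site, translation start). Ti/Tv uses the
standard purine/pyrimidine definition over SNVs.

Immune signatures are scored per sample as the mean cohort z-score over the
set's genes present in the matrix — a deliberately simple single-sample
scorer used only for comparisons between groups; the immune-suppression
comparison uses the same scorer over fibroblast/Treg panels rather than a
reimplementation of ESTIMATE.

The drug model standardizes training (cell-line) expression per gene,
solves ridge regression in closed form on a λ grid, picks λ by k-fold CV
MSE, and maps tumor expression through the *training* means and SDs before
predicting, so predictions are invariant to affine rescaling of any
training gene. Predicting the training-mean profile returns the
training-mean log-IC50 by construction.

## The synthetic cohort

`simulate.generate_cohort` plants, per seed:

* **Subtypes** — K = 4 clusters (multinomial sizes), each with ±3·σ mean
  offsets on a random third of the 24 regulators (σ = the within-cluster
  noise SD, default 1.0 log₂ units). This separation makes subtype recovery
  essentially deterministic at n = 400 — the recovery tests check the
  machinery, not a hard inference problem.
* **DEG blocks** — one 25-gene block per cluster with *graded* cluster
  means (consecutive levels `deg_effect` = 2 log₂-units apart, permuted per
  block), so each block gene clears the two-fold cut in every one-vs-rest
  contrast and the overlap step has a non-trivial planted answer.
* **Score driver** — the standardized mean of the first 10 block genes; it
  multiplies the Weibull hazard (shape 1.2, scale 3000 days, log-HR 0.7 per
  SD) on top of a cluster-specific baseline (the third cluster's scale is
  shrunk 0.4× to emulate a poor-prognosis subtype). Censoring is
  administrative-uniform on [0, τ] with τ solved by bisection so the
  expected censoring fraction hits the configured 30%.
* **Copy-number coupling** — per-sample altered fractions are drawn through
  a Gaussian copula against the driver's normal scores at Pearson
  `2 sin(πρ/6)`, the inversion that yields a target Spearman ρ (default
  −0.22), then mapped through a Beta(1.5, 6) quantile and realized as
  contiguous altered segments on a 22-chromosome, 100 Mb/chromosome toy
  genome. Monte-Carlo error at n = 400 is ~±0.05.
* **Mutations** — Poisson counts (mean 2 nonsynonymous + 0.5 silent per
  sample) with a 2:1 Ti:Tv ratio; immune-signature genes are included in
  the matrix and down-shifted by 1 log₂ unit in the third cluster to give
  the immune-cold contrast.

What the generator does **not** emulate: count-level RNA-seq noise
(expression is Gaussian on the log scale by construction — exactly the
moderated-t working assumption, so DE tests validate the statistics, not
robustness to count noise), focal copy-number architecture, mutation
signatures, batch effects, or correlated gene-gene structure beyond the
planted blocks. Passing tests therefore demonstrate correctness of the
estimators and the pipeline contract on data satisfying the model
assumptions; they do not certify performance on real cohorts.

## Problem sizes and determinism

Statistical acceptance tests run at the planted study conditions —
n = 400–500 samples, 20 seeded replicates for recovery rates, 100
replicates for null-uniformity — with clustering restarted from 3
seedings over K ∈ 1..6 and the lasso path at 30 λ values with 5-fold CV;
these sizes keep each property estimable within a few minutes while leaving
the planted effects comfortably detectable. Every stochastic component
takes an explicit seed, sub-seeds are derived arithmetically (never from
global state), and a pipeline run persists a JSON report that is
byte-identical under re-execution with the same config and seed; `resume`
reloads completed stages from their persisted artifacts.

## Known limitations

* One-vs-rest is the only contrast scheme; no arbitrary design matrices.
* The Lasso-Cox path uses Breslow ties (as glmnet does) while the
  unpenalized fitter defaults to Efron, so the λ = 0 endpoint matches the
  Efron fit only in tie-free data.
* The 1-D score grouping inherits mixture-model sensitivity to skew: a
  heavily skewed unimodal score can be split into two components.
* FGA/aneuploidy treat segment log-ratios symmetrically; gains and losses
  are not distinguished.
* The mean-z signature scorer ignores gene-gene correlation within a set;
  scores are comparable across groups, not across signatures.
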