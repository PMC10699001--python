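# m6atlas

Expression-based subtyping of tumor cohorts by the N6-methyladenosine (m6A)
regulatory machinery, and a per-patient prognostic score derived from the
subtype-defining transcriptional program.

m6A is the most common internal mRNA modification. It is deposited by
*writer* methyltransferases (METTL3/14, WTAP, ZC3H13, VIRMA, CBLL1,
RBM15/RBM15B), removed by the *erasers* FTO and ALKBH5, and interpreted by
14 *reader* proteins (YTH-domain, IGF2BP and hnRNP families, among others).
The joint expression of this 24-gene panel stratifies tumors — thyroid
carcinoma in particular — into subtypes with distinct survival, copy-number
burden and immune microenvironments. `m6atlas` implements that analysis as a
tested, seedable pipeline for bulk expression cohorts:

1. **Subtyping** — Gaussian finite-mixture clustering of the 24 regulator
   genes over six covariance families, with the component count K chosen by
   BIC (`2 log L − p log n`, maximized).
2. **Differential expression** — empirical-Bayes moderated t statistics
   (variance shrinkage `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`, prior fitted
   by moment matching on `log s²_g`) for one-vs-rest subtype contrasts;
   DEGs at adjusted p < 0.05 and |log₂FC| ≥ 1; overlap DEGs across all
   contrasts.
3. **m6Ascore** — overlap DEGs are filtered by a univariate Cox screen
   (p < 0.05); PCA on the surviving signature genes gives per-patient
   projections, and the score is `PC1ᵢ + PC2ᵢ`. Patients are grouped by 1-D
   mixture clustering of the score.
4. **Downstream biology** — fraction genome altered, arm-level aneuploidy
   and tumor mutational burden from SEG/MAF; mean-z immune signature scores
   for the 11 Mariathasan process categories; Spearman / Kruskal–Wallis /
   log-rank associations of the score with each.
5. **Prognostic model** — Lasso-penalized Cox regression (coordinate
   descent, cross-validated λ) over the signature genes; median-split risk
   groups; IPCW time-dependent AUC at 1/2/3 years.
6. **Drug sensitivity transfer** — a ridge model of log-IC50 trained on
   cell-line expression and applied to tumors through the training
   standardization (Cisplatin and Paclitaxel panels by default).

A seeded synthetic-cohort generator (`m6atlas.simulate`) plants all the
structure the analysis assumes — regulator subtypes, graded DEG blocks, a
survival-driving score, a copy-number burden rank-coupled to the score at a
target Spearman ρ — so every stage is testable end to end without any data
download.

## Worked example

```python
from m6atlas import de, mixture, score as scoring, survival
from m6atlas.catalog import load_regulator_catalog
from m6atlas.simulate import SimulationConfig, generate_cohort

# 1. simulate a 300-patient cohort with 4 planted regulator subtypes
X, clinical, segs, muts, truth = generate_cohort(SimulationConfig(n_samples=300, seed=1))

# 2. model-based clustering of the 24-gene regulator panel
panel = load_regulator_catalog().symbols
M = X.values.loc[panel].to_numpy().T
M = (M - M.mean(axis=0)) / M.std(axis=0)
model, clusters, bic_table = mixture.select_model(
    M, k_range=range(1, 7), seed=1, n_init=3, sample_ids=X.sample_ids
)

# 3. one-vs-rest moderated DE and overlap DEGs
stats = de.moderated_stats(X, clusters)
overlap = de.overlap_degs([de.deg_set(s) for s in stats.values()])

# 4. prognostic screen and the PCA score
_, significant = survival.univariate_screen(X, clinical, sorted(overlap))
genes = scoring.select_signature_genes(overlap, significant)
result = scoring.compute_m6ascore(scoring.pca_signature(X, genes))
groups, _ = scoring.score_groups(result.scores, seed=1)

# 5. survival by score group
chi2, df, p = survival.logrank_test(clinical, groups)
```

Output:

```
selected K = 4 (diagonal-equal), cluster sizes = [88, 81, 66, 65]
overlap DEGs (adj p < 0.05, |log2FC| >= 1): 78
signature genes: 59; score groups: [147, 69, 84]
log-rank across score groups: chi2 = 23.9 (df 2), p = 6.37e-06
```

BIC selects the planted four subtypes; 78 genes are consistently
differentially expressed across every subtype-vs-rest contrast, 59 of them
carry prognostic signal, and the resulting score separates patients into
groups with clearly different overall survival.

The same analysis runs as a staged, resumable pipeline from a YAML config:

```bash
m6atlas run --config config.yaml --seed 7 --outdir out/
```

with subcommands (`simulate`, `cluster`, `deg`, `score`, `survival`,
`burden`, `drugs`) for individual stages. Real cohorts enter as a
genes × samples TSV on the log₂(FPKM+1) scale, a clinical TSV with
`os_time`/`os_event`, SEG segments, a minimal MAF and optional GMT gene
sets.

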