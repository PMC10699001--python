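"""PCA-based per-patient scoring over the prognostic overlap-DEG signature.

The signature genes are the overlap DEGs that also pass a univariate Cox
screen.  PCA is run on the centered (optionally scaled) signature expression
across samples, and each patient's score is the sum of their PC1 and PC2
projections — a Genomic-Grade-Index-style construction.  Score groups come
from 1-D mixture-model clustering of the scores, labelled by ascending
group mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mixture
from .io import ClinicalTable, ExpressionMatrix
from .survival import km_estimate, kruskal_wallis, logrank_test, spearman

__all__ = [
    "SignatureProjection",
    "M6AScoreResult",
    "select_signature_genes",
    "pca_signature",
    "compute_m6ascore",
    "score_groups",
    "score_associations",
]


@dataclass
class SignatureProjection:
    genes: list[str]
    center: pd.Series
    scale: pd.Series | None
    loadings: pd.DataFrame       # genes x [PC1, PC2], unit norm
    projections: pd.DataFrame    # samples x [PC1, PC2]
    explained_variance_ratio: np.ndarray


@dataclass
class M6AScoreResult:
    scores: pd.Series                       # per-sample PC1 + PC2
    projections: pd.DataFrame
    signature_genes: list[str]
    score_group: pd.Series | None = None
    provenance: dict = field(default_factory=dict)


def select_signature_genes(overlap_degs: set[str], significant: set[str]) -> list[str]:
    """Overlap DEGs that are also Cox-significant, sorted for determinism."""
    genes = sorted({g.upper() for g in overlap_degs} & {g.upper() for g in significant})
    if not genes:
        raise ValueError(
            "no overlap DEG passed the prognostic screen; relax alpha or fold-change thresholds"
        )
    return genes


def pca_signature(
    X: ExpressionMatrix,
    signature_genes: list[str],
    scale: bool = False,
) -> SignatureProjection:
    """PCA of the signature-gene expression across samples.

    Genes are centered (and optionally unit-scaled) across the cohort; the
    eigenvectors of the sample covariance give the loadings.  Each loading's
    sign is fixed by orienting its largest-absolute-weight entry positive,
    removing eigenvector sign ambiguity.
    """
    genes = [g.upper() for g in signature_genes]
    if len(genes) < 2:
        raise ValueError("need at least 2 signature genes")
    if len(X.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    sub = X.values.loc[genes]  # genes x samples
    variances = sub.var(axis=1, ddof=0)
    dropped = list(variances.index[variances == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance signature genes: {dropped}", RuntimeWarning)
        sub = sub.drop(index=dropped)
        genes = [g for g in genes if g not in dropped]
        if len(genes) < 2:
            raise ValueError("fewer than 2 signature genes with non-zero variance")
    M = sub.to_numpy(float).T  # samples x genes
    center = M.mean(axis=0)
    Mc = M - center
    scale_vec = None
    if scale:
        scale_vec = Mc.std(axis=0, ddof=0)
        Mc = Mc / scale_vec
    # SVD of the centered matrix: right singular vectors = PC loadings
    _, s_vals, Vt = np.linalg.svd(Mc, full_matrices=False)
    n_pc = min(2, Vt.shape[0])
    loadings = Vt[:n_pc].T  # genes x PCs
    if n_pc < 2:
        loadings = np.hstack([loadings, np.zeros((loadings.shape[0], 1))])
        s_vals = np.append(s_vals, 0.0)
    loadings = loadings[:, :2].copy()
    for j in range(2):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    proj = Mc @ loadings
    total_var = (s_vals**2).sum()
    evr = (s_vals[:2] ** 2) / total_var if total_var > 0 else np.zeros(2)
    return SignatureProjection(
        genes=genes,
        center=pd.Series(center, index=genes),
        scale=pd.Series(scale_vec, index=genes) if scale_vec is not None else None,
        loadings=pd.DataFrame(loadings, index=genes, columns=["PC1", "PC2"]),
        projections=pd.DataFrame(proj, index=X.sample_ids, columns=["PC1", "PC2"]),
        explained_variance_ratio=evr,
    )


def compute_m6ascore(proj: SignatureProjection) -> M6AScoreResult:
    """Per-sample score = PC1 projection + PC2 projection."""
    scores = proj.projections["PC1"] + proj.projections["PC2"]
    scores.name = "m6ascore"
    return M6AScoreResult(
        scores=scores,
        projections=proj.projections,
        signature_genes=proj.genes,
        provenance={
            "n_signature_genes": len(proj.genes),
            "explained_variance_ratio": list(map(float, proj.explained_variance_ratio)),
        },
    )


def score_groups(
    scores: pd.Series,
    seed: int = 0,
    k_range: range | list[int] = range(1, 7),
    n_init: int = 5,
) -> tuple[pd.Series, mixture.MixtureModel]:
    """1-D mixture-model grouping of scores; labels ordered by ascending mean."""
    if len(scores) < 10:
        raise ValueError("need at least 10 samples to group scores")
    if scores.nunique() == 1:
        raise mixture.DegenerateFitError("scores are constant; grouping undefined")
    x = scores.to_numpy(float)[:, None]
    model, _, _ = mixture.select_model(
        x,
        k_range=k_range,
        structures=("spherical-equal", "spherical-varying"),
        seed=seed,
        n_init=n_init,
    )
    assignment = mixture.assign(model, x, sample_ids=list(scores.index))
    # reorder labels by ascending component mean rather than size
    raw = assignment.labels
    means = {lbl: scores[raw == lbl].mean() for lbl in sorted(raw.unique())}
    order = sorted(means, key=lambda l: means[l])
    remap = {old: new for new, old in enumerate(order, start=1)}
    return raw.map(remap).rename("score_group"), model


def score_associations(
    result: M6AScoreResult,
    burden_table: pd.DataFrame | None = None,
    signature_scores: pd.DataFrame | None = None,
    clinical: ClinicalTable | None = None,
    cluster_labels: pd.Series | None = None,
) -> dict:
    """Associations of the score with burden metrics, clusters and survival.

    Returns a dict with Spearman correlations against each burden metric,
    Kruskal-Wallis of the score across expression clusters, log-rank across
    score groups, and group means of the immune signature scores.
    """
    report: dict = {}
    scores = result.scores
    if burden_table is not None:
        shared = scores.index.intersection(burden_table.index)
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared samples with the burden table")
        report["burden_spearman"] = {}
        for col in burden_table.columns:
            vals = burden_table.loc[shared, col]
            ok = vals.notna()
            rho, p = spearman(scores[shared][ok].to_numpy(), vals[ok].to_numpy())
            report["burden_spearman"][col] = {"rho": rho, "p": p}
    if cluster_labels is not None:
        shared = scores.index.intersection(cluster_labels.index)
        H, df, p = kruskal_wallis(scores[shared].to_numpy(), cluster_labels[shared].to_numpy())
        report["kruskal_across_clusters"] = {"H": H, "df": df, "p": p}
    if clinical is not None and result.score_group is not None:
        shared = [s for s in result.score_group.index if s in clinical.data.index]
        groups = result.score_group[shared]
        if groups.nunique() >= 2:
            clin = ClinicalTable(clinical.data.loc[shared])
            chi2, df, p = logrank_test(clin, groups)
            report["logrank_score_groups"] = {"chi2": chi2, "df": df, "p": p}
            report["km_curves"] = {
                g: {"times": c.times.tolist(), "survival": c.survival.tolist()}
                for g, c in km_estimate(clin, groups).items()
            }
        else:
            report["logrank_score_groups"] = {"note": "single score group; test skipped"}
    if signature_scores is not None and result.score_group is not None:
        shared = signature_scores.index.intersection(result.score_group.index)
        grp = result.score_group[shared]
        report["signature_group_means"] = (
            signature_scores.loc[shared].groupby(grp).mean().to_dict()
        )
    return report
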