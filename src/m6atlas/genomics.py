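"""Copy-number burden, mutation metrics, immune signature scores and the
ridge drug-sensitivity transfer model.

Burden metrics follow the common conventions: fraction genome altered (FGA)
is the covered-length fraction with |log2 ratio| above a threshold
(cBioPortal-style, default 0.2); the aneuploidy score is an arm-level count
(an arm is altered when at least ``arm_fraction`` of its covered length is
altered); TMB is qualifying mutations per megabase of exome (default 38 Mb,
nonsynonymous classes only).  Immune signatures are scored per sample as the
mean cohort z-score over the set's genes present in the matrix.

The drug model standardizes training (cell-line) expression, solves ridge
regression in closed form over a penalty grid with k-fold CV, and maps tumor
expression through the training standardization before predicting log-IC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    MutationTable,
    SegmentTable,
    NONSYNONYMOUS_CLASSES,
)

__all__ = [
    "BurdenTable",
    "RidgeDrugModel",
    "fraction_genome_altered",
    "aneuploidy_score",
    "tmb",
    "titv_ratio",
    "burden_table",
    "signature_scores",
    "train_drug_model",
    "predict_ic50",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class BurdenTable:
    data: pd.DataFrame  # index sample; columns fga, aneuploidy_score, tmb


@dataclass
class RidgeDrugModel:
    drug: str
    genes: list[str]
    train_mean: pd.Series
    train_sd: pd.Series
    coefficients: pd.Series
    intercept: float
    penalty: float
    cv_table: pd.DataFrame


def fraction_genome_altered(
    segs: SegmentTable,
    threshold: float = 0.2,
) -> pd.Series:
    """Per-sample FGA: altered covered length / total covered length.

    A segment is altered when |log2 ratio| > threshold.  Samples with no
    segments are absent from the result (callers see NA on reindex).
    """
    df = segs.data.copy()
    df["length"] = df["end"] - df["start"] + 1
    df["altered"] = (df["log2_ratio"].abs() > threshold) * df["length"]
    g = df.groupby("sample_id")
    fga = g["altered"].sum() / g["length"].sum()
    fga.name = "fga"
    return fga


def aneuploidy_score(
    segs: SegmentTable,
    arm_table: pd.DataFrame,
    arm_fraction: float = 0.5,
    threshold: float = 0.2,
) -> pd.Series:
    """Arm-level aneuploidy count: arms with >= arm_fraction altered coverage."""
    merged = segs.data.merge(
        arm_table.rename(columns={"start": "arm_start", "end": "arm_end"}),
        on="chrom",
        how="inner",
    )
    start = np.maximum(merged["start"], merged["arm_start"])
    end = np.minimum(merged["end"], merged["arm_end"])
    merged["ov_len"] = np.maximum(end - start + 1, 0)
    merged["ov_alt"] = merged["ov_len"] * (merged["log2_ratio"].abs() > threshold)
    g = merged.groupby(["sample_id", "arm"])[["ov_len", "ov_alt"]].sum()
    covered = g[g["ov_len"] > 0]
    altered_arm = covered["ov_alt"] / covered["ov_len"] >= arm_fraction
    s = altered_arm.groupby("sample_id").sum().astype(int)
    s = s.reindex(segs.data["sample_id"].unique(), fill_value=0)
    s.name = "aneuploidy_score"
    s.index.name = "sample_id"
    return s


def tmb(
    muts: MutationTable,
    exome_mb: float = 38.0,
    nonsynonymous_only: bool = True,
    samples: list[str] | None = None,
) -> pd.Series:
    """Tumor mutational burden: qualifying mutations per Mb of exome."""
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    df = muts.data
    if nonsynonymous_only:
        df = df[df["variant_classification"].isin(NONSYNONYMOUS_CLASSES)]
    counts = df.groupby("sample_id").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    out = counts / exome_mb
    out.name = "tmb"
    return out.astype(float)


def titv_ratio(muts: MutationTable) -> float:
    """Transitions / transversions over SNVs (requires ref/alt allele columns)."""
    df = muts.data
    if "ref_allele" not in df.columns or "alt_allele" not in df.columns:
        raise ValueError("Ti/Tv requires ref_allele and alt_allele columns")
    snv = df[(df["ref_allele"].str.len() == 1) & (df["alt_allele"].str.len() == 1)]
    pairs = list(zip(snv["ref_allele"].str.upper(), snv["alt_allele"].str.upper()))
    ti = sum(p in TRANSITIONS for p in pairs)
    tv = len(pairs) - ti
    if tv == 0:
        return float("inf") if ti else float("nan")
    return ti / tv


def burden_table(
    segs: SegmentTable,
    muts: MutationTable,
    arm_table: pd.DataFrame,
    samples: list[str],
    fga_threshold: float = 0.2,
    arm_fraction: float = 0.5,
    exome_mb: float = 38.0,
) -> BurdenTable:
    """Assemble FGA / aneuploidy / TMB for the given samples (NA where absent)."""
    fga = fraction_genome_altered(segs, fga_threshold).reindex(samples)
    if fga.isna().any():
        warnings.warn(
            f"{int(fga.isna().sum())} samples lack copy-number segments (NA FGA)",
            RuntimeWarning,
        )
    aneu = aneuploidy_score(segs, arm_table, arm_fraction, fga_threshold).reindex(samples)
    t = tmb(muts, exome_mb, samples=samples)
    return BurdenTable(pd.DataFrame({"fga": fga, "aneuploidy_score": aneu, "tmb": t}))


# ---------------------------------------------------------------------------
# Immune signature scoring
# ---------------------------------------------------------------------------

def signature_scores(X: ExpressionMatrix, sets) -> pd.DataFrame:
    """Mean cohort z-score per sample for every gene set.

    Per-gene z across the cohort, then the average over set members present
    in the matrix; zero-variance genes are excluded, empty sets give NA
    columns with a warning.
    """
    set_map = sets.sets if hasattr(sets, "sets") else sets
    vals = X.values
    sd = vals.std(axis=1, ddof=0)
    usable = sd > 0
    z = vals.loc[usable].sub(vals.loc[usable].mean(axis=1), axis=0).div(sd[usable], axis=0)
    out = {}
    for name, genes in set_map.items():
        members = [g for g in {g.upper() for g in genes} if g in z.index]
        if not members:
            warnings.warn(f"signature {name!r} shares no usable genes with the matrix", RuntimeWarning)
            out[name] = pd.Series(np.nan, index=vals.columns)
            continue
        out[name] = z.loc[members].mean(axis=0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Ridge drug-sensitivity transfer model
# ---------------------------------------------------------------------------

def _ridge_solve(Xs: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    n, p = Xs.shape
    A = Xs.T @ Xs + lam * np.eye(p)
    return np.linalg.solve(A, Xs.T @ y)


def train_drug_model(
    cell_expr: ExpressionMatrix,
    ic50: pd.DataFrame,
    drug: str,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> RidgeDrugModel:
    """Fit the ridge log-IC50 model on cell-line expression.

    Genes are standardized on the training lines (constant genes dropped);
    ridge coefficients are solved in closed form for each penalty and the
    penalty minimizing k-fold CV mean squared error is kept.
    """
    if drug not in ic50.columns:
        raise ValueError(f"drug {drug!r} not in IC50 table")
    lines = [s for s in cell_expr.sample_ids if s in ic50.index]
    if len(lines) < n_folds:
        raise ValueError(f"only {len(lines)} lines for {n_folds} folds")
    y = ic50.loc[lines, drug].to_numpy(float)
    Xmat = cell_expr.values[lines].to_numpy(float).T  # lines x genes
    genes = cell_expr.gene_ids
    mu = Xmat.mean(axis=0)
    sd = Xmat.std(axis=0)
    keep = sd > 0
    genes = [g for g, k in zip(genes, keep) if k]
    Xs = (Xmat[:, keep] - mu[keep]) / sd[keep]
    y_mean = y.mean()
    yc = y - y_mean
    n = len(lines)
    if lambda_grid is None:
        lambda_grid = np.geomspace(1e-4 * n, 1e4 * n, 41)
    lambda_grid = np.asarray(lambda_grid, float)

    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % n_folds
    cv_mse = np.zeros(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        sse = 0.0
        for f in range(n_folds):
            tr = folds != f
            b = _ridge_solve(Xs[tr], yc[tr], lam)
            pred = Xs[~tr] @ b
            sse += ((yc[~tr] - pred) ** 2).sum()
        cv_mse[i] = sse / n
    best = int(np.argmin(cv_mse))
    lam = float(lambda_grid[best])
    beta = _ridge_solve(Xs, yc, lam)
    return RidgeDrugModel(
        drug=drug,
        genes=genes,
        train_mean=pd.Series(mu[keep], index=genes),
        train_sd=pd.Series(sd[keep], index=genes),
        coefficients=pd.Series(beta, index=genes),
        intercept=float(y_mean),
        penalty=lam,
        cv_table=pd.DataFrame({"lambda": lambda_grid, "cv_mse": cv_mse}),
    )


def predict_ic50(model: RidgeDrugModel, tumor_expr: ExpressionMatrix) -> pd.Series:
    """Predicted log-IC50 per tumor via the training standardization.

    Only genes shared with the training panel contribute; tumor values are
    centered/scaled with the *training* means and SDs.
    """
    shared = [g for g in model.genes if g in tumor_expr.values.index]
    if not shared:
        raise ValueError("no genes shared between drug model and tumor matrix")
    M = tumor_expr.values.loc[shared].to_numpy(float).T  # tumors x genes
    Ms = (M - model.train_mean[shared].to_numpy()) / model.train_sd[shared].to_numpy()
    pred = Ms @ model.coefficients[shared].to_numpy() + model.intercept
    return pd.Series(pred, index=tumor_expr.sample_ids, name=f"ic50_{model.drug}")
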