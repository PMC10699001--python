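"""Moderated differential expression among expression subtypes.

Implements the empirical-Bayes moderated t pipeline for one-vs-rest
contrasts: a per-gene two-group linear model gives the residual variance
``s2_g`` with ``d_g`` degrees of freedom; an inverse-chi-square prior
``(d0, s0^2)`` is estimated by moment matching on ``log s2_g`` (Smyth 2004,
the limma procedure), and the shrunken variance

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

replaces ``s2_g`` in the t statistic, which then has ``d0 + d_g`` degrees of
freedom.  DEG calling follows the adjusted-p < alpha and |log2FC| >= cutoff
convention, with Benjamini-Hochberg adjustment within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .mixture import ClusterAssignment

__all__ = [
    "DEStatTable",
    "moderated_stats",
    "fit_variance_prior",
    "trigamma_inverse",
    "bh_adjust",
    "call_degs",
    "overlap_degs",
    "ora_enrichment",
]

VAR_FLOOR = 1e-8


@dataclass
class DEStatTable:
    """Per-gene moderated statistics for one contrast (cluster k vs rest)."""

    contrast: str
    table: pd.DataFrame  # index gene; mean_group, mean_rest, log2_fc, s2, df,
    #                      s2_tilde, t, p, adj_p, zero_variance
    d0: float
    s0_sq: float


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches the mean and variance of ``log s2_g`` against the scaled-F
    distribution implied by the hierarchical model; returns d0 = inf when
    the observed spread of log-variances is no larger than expected under a
    common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(np.maximum(s2, VAR_FLOOR))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    resid = evar - special.polygamma(1, df / 2.0)
    if resid <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(resid)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def _one_contrast(
    X: np.ndarray,
    in_group: np.ndarray,
    genes: list[str],
    contrast: str,
    d0_override: float | None,
) -> DEStatTable:
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    n = n1 + n2
    m1 = X[:, in_group].mean(axis=1)
    m2 = X[:, ~in_group].mean(axis=1)
    # pooled two-group residual variance, df = n - 2
    rss = ((X[:, in_group] - m1[:, None]) ** 2).sum(axis=1) + (
        (X[:, ~in_group] - m2[:, None]) ** 2
    ).sum(axis=1)
    df = n - 2
    s2 = rss / df
    zero_var = s2 < VAR_FLOOR
    s2 = np.maximum(s2, VAR_FLOOR)

    usable = s2[~zero_var] if (~zero_var).any() else s2
    if d0_override is not None:
        d0 = d0_override
        s0_sq = float(np.exp(np.mean(np.log(usable))))
    else:
        d0, s0_sq = fit_variance_prior(usable, df)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    log2_fc = m1 - m2
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    t = log2_fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "mean_group": m1,
            "mean_rest": m2,
            "log2_fc": log2_fc,
            "s2": s2,
            "df": df,
            "s2_tilde": s2_tilde,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "zero_variance": zero_var,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEStatTable(contrast=contrast, table=table, d0=d0, s0_sq=s0_sq)


def moderated_stats(
    X: ExpressionMatrix,
    labels: ClusterAssignment | pd.Series,
    contrast_scheme: str = "one_vs_rest",
    d0_override: float | None = None,
) -> dict[str, DEStatTable]:
    """Moderated t statistics for every one-vs-rest cluster contrast.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary pooled t; ``numpy.inf`` fully shrinks every variance to s0^2);
    by default the prior is estimated from the data.
    """
    if contrast_scheme != "one_vs_rest":
        raise ValueError(f"unsupported contrast scheme {contrast_scheme!r}")
    lab = labels.labels if isinstance(labels, ClusterAssignment) else labels
    lab = lab.reindex(X.sample_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need at least two clusters for differential expression")
    counts = lab.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"cluster {small.index[0]} has fewer than 2 samples")
    arr = X.values.to_numpy()
    out: dict[str, DEStatTable] = {}
    for g in groups:
        mask = (lab == g).to_numpy()
        out[f"c{g}_vs_rest"] = _one_contrast(
            arr, mask, X.gene_ids, f"c{g}_vs_rest", d0_override
        )
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    stat: DEStatTable,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """DEG calls at adj p < alpha (strict) and |log2FC| >= min_abs_log2fc.

    Returns the stat table augmented with a ``passes`` column and the
    thresholds used; the default fold-change cut of 1 log2 unit is the
    two-fold convention.
    """
    t = stat.table.copy()
    t["passes"] = (t["adj_p"] < alpha) & (t["log2_fc"].abs() >= min_abs_log2fc)
    t["alpha"] = alpha
    t["min_abs_log2fc"] = min_abs_log2fc
    return t


def deg_set(stat: DEStatTable, alpha: float = 0.05, min_abs_log2fc: float = 1.0) -> set[str]:
    t = call_degs(stat, alpha, min_abs_log2fc)
    return set(t.index[t["passes"]])


def overlap_degs(
    per_contrast_sets: list[set[str]],
    mode: str = "intersection",
    min_contrasts: int | None = None,
) -> set[str]:
    """Genes called in all contrasts (or in >= min_contrasts of them)."""
    if not per_contrast_sets:
        raise ValueError("need at least one contrast DEG set")
    if min_contrasts is not None:
        counts: dict[str, int] = {}
        for s in per_contrast_sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        return {g for g, c in counts.items() if c >= min_contrasts}
    if mode != "intersection":
        raise ValueError(f"unknown overlap mode {mode!r}")
    out = set(per_contrast_sets[0])
    for s in per_contrast_sets[1:]:
        out &= s
    return out


def ora_enrichment(query: set[str], sets, universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|set & universe|,
    n=|query|); BH adjustment across sets.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = {g.upper() for g in query} & universe
    N = len(universe)
    n = len(query)
    rows = []
    set_map = sets.sets if hasattr(sets, "sets") else sets
    for name, genes in set_map.items():
        genes = {g.upper() for g in genes} & universe
        K = len(genes)
        overlap = len(query & genes)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n)) if K else 1.0
        rows.append((name, K, overlap, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values("p")
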