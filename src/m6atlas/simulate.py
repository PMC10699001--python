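"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

A cohort carries:

* K latent expression subtypes planted on the 24-gene regulator panel
  (per-cluster mean offsets in units of the within-cluster SD);
* one DEG block per cluster whose genes take *graded* cluster means
  (consecutive levels ``deg_effect`` log2-units apart, permuted per block)
  so each block gene is differentially expressed in every one-vs-rest
  contrast — the structure the overlap-DEG step expects;
* immune-signature gene blocks (the registry panels), down-shifted in one
  "immune-cold" cluster;
* a per-sample score driver (standardized mean of the planted prognostic
  genes) that multiplies the Weibull hazard and is rank-coupled to
  copy-number burden at a target Spearman correlation (default -0.22);
* per-sample SEG segments realizing the planted altered fraction, and
  Poisson mutation counts in a minimal MAF.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import load_regulator_catalog, signature_registry
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    SegmentTable,
    toy_genome,
)

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "PanelTruth",
    "generate_cohort",
    "generate_cell_line_panel",
    "generate_gene_sets",
]


@dataclass
class SimulationConfig:
    n_samples: int = 400
    n_genes: int = 1000
    n_clusters: int = 4
    regulator_shift: float = 3.0        # cluster offsets on regulators, units of noise_sd
    deg_block_size: int = 25
    deg_effect: float = 2.0             # log2-units between consecutive cluster levels
    n_prognostic: int = 10
    noise_sd: float = 1.0
    immune_shift: float = 1.0           # down-shift of signature genes in the cold cluster
    weibull_shape: float = 1.2
    weibull_scale: float = 3000.0       # days; baseline survival scale
    poor_cluster_scale: float = 0.4     # hazard-scale multiplier for the poor-prognosis cluster
    score_log_hr: float = 0.7           # log hazard ratio per SD of the score driver
    censoring_rate: float = 0.3
    planted_rho: float = -0.22          # target Spearman(score driver, FGA)
    mutation_rate: float = 2.0          # mean nonsynonymous mutations per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < self.n_clusters:
            raise ValueError("n_samples must be >= n_clusters")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not (-1.0 <= self.planted_rho <= 1.0):
            raise ValueError("planted_rho must be in [-1, 1]")
        for name in ("n_genes", "deg_block_size", "n_prognostic", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortTruth:
    true_labels: pd.Series
    planted_deg_genes: set[str]
    planted_prognostic_genes: set[str]
    planted_score: pd.Series
    planted_rho: float
    deg_block_map: dict[str, list[str]]
    seed: int


@dataclass
class PanelTruth:
    weights: pd.DataFrame  # genes x drugs
    noise_sd: float
    seed: int


def _cluster_levels(K: int) -> np.ndarray:
    """Graded per-cluster levels with min |level| = 0.5 (even or odd K)."""
    v = np.arange(K, dtype=float) - (K - 1) / 2.0
    if K % 2 == 1:
        v += 0.5
    return v


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SegmentTable, MutationTable, CohortTruth]:
    """Generate one synthetic cohort; identical config+seed is byte-identical."""
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_clusters
    n = cfg.n_samples

    catalog = load_regulator_catalog()
    regulators = catalog.symbols
    registry = signature_registry(include_extended=True)
    sig_genes = sorted(set().union(*registry.values()))
    n_deg = K * cfg.deg_block_size
    n_fixed = len(regulators) + n_deg + len(sig_genes)
    if n_fixed >= cfg.n_genes:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small: need > {n_fixed} "
            "(regulators + DEG blocks + signature panels)"
        )
    deg_block_map = {
        f"BLOCK{k}": [f"DEG{k}_{j}" for j in range(cfg.deg_block_size)]
        for k in range(1, K + 1)
    }
    deg_genes = [g for genes in deg_block_map.values() for g in genes]
    noise_genes = [f"NOISE{j}" for j in range(cfg.n_genes - n_fixed)]
    genes = regulators + deg_genes + sig_genes + noise_genes

    sample_ids = [f"P{i:04d}" for i in range(n)]
    labels = rng.integers(1, K + 1, size=n)
    # guarantee every cluster is populated
    for k in range(1, K + 1):
        if not (labels == k).any():
            labels[rng.integers(0, n)] = k
    labels = pd.Series(labels, index=sample_ids, name="true_label")

    G = len(genes)
    base = rng.uniform(2.0, 8.0, size=G)
    gi = {g: i for i, g in enumerate(genes)}
    for g in regulators:
        base[gi[g]] = rng.uniform(5.0, 9.0)

    # per-cluster mean offsets
    offsets = np.zeros((K, G))
    reg_pattern = rng.choice([-1.0, 0.0, 1.0], size=(K, len(regulators)))
    for k in range(K):
        for j, g in enumerate(regulators):
            offsets[k, gi[g]] = cfg.regulator_shift * cfg.noise_sd * reg_pattern[k, j]
    levels = _cluster_levels(K)
    for b, (_, block_genes) in enumerate(deg_block_map.items()):
        perm = rng.permutation(K)
        for g in block_genes:
            offsets[:, gi[g]] = cfg.deg_effect * levels[perm]
    cold = min(3, K) - 1  # 0-based index of the immune-cold cluster
    for g in sig_genes:
        offsets[cold, gi[g]] = -cfg.immune_shift

    noise = rng.normal(0.0, cfg.noise_sd, size=(G, n))
    expr = base[:, None] + offsets[labels.to_numpy() - 1].T + noise
    expr = np.clip(expr, 0.0, None)
    X = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=sample_ids), scale_tag="log2p1"
    )

    # score driver: standardized mean of the planted prognostic genes
    prog_genes = deg_genes[: cfg.n_prognostic]
    drv = X.values.loc[prog_genes].mean(axis=0)
    score = (drv - drv.mean()) / drv.std(ddof=0)
    score.name = "planted_score"

    clinical = _simulate_survival(cfg, rng, labels, score)
    segs = _simulate_segments(cfg, rng, score)
    muts = _simulate_mutations(cfg, rng, sample_ids, genes)

    truth = CohortTruth(
        true_labels=labels,
        planted_deg_genes=set(deg_genes),
        planted_prognostic_genes=set(prog_genes),
        planted_score=score,
        planted_rho=cfg.planted_rho,
        deg_block_map=deg_block_map,
        seed=cfg.seed,
    )
    return X, clinical, segs, muts, truth


def _simulate_survival(cfg, rng, labels, score) -> ClinicalTable:
    n = len(labels)
    scales = np.full(cfg.n_clusters, cfg.weibull_scale)
    scales[min(3, cfg.n_clusters) - 1] *= cfg.poor_cluster_scale  # poor-prognosis cluster
    lam = scales[labels.to_numpy() - 1]
    hazard_mult = np.exp(cfg.score_log_hr * score.to_numpy())
    u = rng.uniform(size=n)
    T = lam * (-np.log(u) / hazard_mult) ** (1.0 / cfg.weibull_shape)
    if cfg.censoring_rate == 0.0:
        time, event = T, np.ones(n, dtype=int)
    else:
        tau = _calibrate_tau(T, cfg.censoring_rate)
        C = rng.uniform(0.0, tau, size=n)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    df = pd.DataFrame(
        {"os_time": time, "os_event": event, "cluster": labels.to_numpy()},
        index=labels.index,
    )
    return ClinicalTable(df)


def _calibrate_tau(T: np.ndarray, rate: float) -> float:
    """Administrative censoring horizon: E[fraction censored] = rate.

    With C ~ U(0, tau), P(censored_i) = min(T_i / tau, 1); solved by bisection.
    """
    lo, hi = T.min() * 1e-3 + 1e-9, T.max() * 1e4

    def frac(tau):
        return np.minimum(T / tau, 1.0).mean()

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_segments(cfg, rng, score) -> SegmentTable:
    """Per-sample SEG with altered fraction rank-coupled to -score.

    The target Spearman rho is hit in expectation by mixing the normal
    scores of the driver with independent noise at the Pearson correlation
    ``2 sin(pi rho / 6)`` (the Gaussian-copula inversion), then mapping the
    latent burden through a Beta(1.5, 6) quantile to an altered fraction.
    """
    n = len(score)
    genome = toy_genome()
    rho_p = 2.0 * np.sin(np.pi * cfg.planted_rho / 6.0)
    ranks = stats.rankdata(score.to_numpy())
    z = stats.norm.ppf(ranks / (n + 1.0))
    eps = rng.normal(size=n)
    latent = rho_p * z + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
    fga = stats.beta.ppf(stats.norm.cdf(latent), 1.5, 6.0)

    chroms = list(genome)
    total = sum(genome.values())
    rows = []
    for s, f in zip(score.index, fga):
        remaining = f * total
        for chrom in chroms:
            L = genome[chrom]
            alt = int(min(L, max(0.0, remaining)))
            remaining -= alt
            if alt >= 1:
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                rows.append((s, chrom, 1, alt, sign * 0.6))
                if alt < L:
                    rows.append((s, chrom, alt + 1, L, 0.0))
            else:
                rows.append((s, chrom, 1, L, 0.0))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "log2_ratio"])
    return SegmentTable(df)


def _simulate_mutations(cfg, rng, sample_ids, genes) -> MutationTable:
    nonsyn_classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]
    bases = np.array(list("ACGT"))
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    rows = []
    for s in sample_ids:
        n_ns = rng.poisson(cfg.mutation_rate)
        n_silent = rng.poisson(cfg.mutation_rate / 4.0)
        for kind, count in (("nonsyn", n_ns), ("silent", n_silent)):
            for _ in range(count):
                gene = genes[rng.integers(0, len(genes))]
                vc = (
                    nonsyn_classes[rng.integers(0, len(nonsyn_classes))]
                    if kind == "nonsyn"
                    else "Silent"
                )
                ref = bases[rng.integers(0, 4)]
                if rng.uniform() < 2.0 / 3.0:  # Ti:Tv ~ 2:1
                    alt = transitions[ref]
                else:
                    alt = rng.choice([b for b in bases if b != ref and b != transitions[ref]])
                rows.append((s, gene, vc, ref, alt))
    df = pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_classification", "ref_allele", "alt_allele"]
    )
    if df.empty:
        df = pd.DataFrame(
            columns=["sample_id", "gene", "variant_classification", "ref_allele", "alt_allele"]
        )
    return MutationTable(df)


def generate_cell_line_panel(
    n_lines: int = 200,
    n_genes: int = 50,
    weight_sparsity: float = 0.2,
    noise_sd: float = 0.5,
    seed: int = 0,
    gene_names: list[str] | None = None,
    drugs: tuple[str, ...] = ("Cisplatin", "Paclitaxel"),
) -> tuple[ExpressionMatrix, pd.DataFrame, PanelTruth]:
    """Cell-line expression panel with planted linear log-IC50 responses.

    ``log_ic50 = (x - mean_g) . w + eps`` with sparse weights w (fraction
    ``weight_sparsity`` nonzero, N(0,1) values).
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_genes == 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    genes = gene_names if gene_names is not None else [f"G{j}" for j in range(n_genes)]
    n_genes = len(genes)
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    base = rng.uniform(2.0, 8.0, size=n_genes)
    expr = np.clip(base[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_lines)), 0.0, None)
    X = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=lines), scale_tag="log2p1")
    Xc = expr - expr.mean(axis=1, keepdims=True)
    w = np.zeros((n_genes, len(drugs)))
    n_active = max(1, int(round(weight_sparsity * n_genes)))
    for j in range(len(drugs)):
        idx = rng.choice(n_genes, size=n_active, replace=False)
        w[idx, j] = rng.normal(0.0, 1.0, size=n_active)
    ic50 = Xc.T @ w + rng.normal(0.0, noise_sd, size=(n_lines, len(drugs)))
    ic50_df = pd.DataFrame(ic50, index=lines, columns=list(drugs))
    truth = PanelTruth(
        weights=pd.DataFrame(w, index=X.gene_ids, columns=list(drugs)),
        noise_sd=noise_sd,
        seed=seed,
    )
    return X, ic50_df, truth


def generate_gene_sets(
    deg_block_map: dict[str, list[str]],
    n_decoy_sets: int = 4,
    seed: int = 0,
    noise_genes: list[str] | None = None,
) -> GeneSetCollection:
    """One gene set per planted DEG block plus size-matched decoys of noise genes."""
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {name: set(genes) for name, genes in deg_block_map.items()}
    sizes = [len(g) for g in deg_block_map.values()] or [10]
    pool = noise_genes or [f"NOISE{j}" for j in range(2000)]
    for i in range(n_decoy_sets):
        size = sizes[i % len(sizes)]
        sets[f"DECOY{i}"] = set(rng.choice(pool, size=size, replace=False))
    return GeneSetCollection(sets)
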