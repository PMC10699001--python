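"""Gaussian finite-mixture clustering with BIC model selection.

Model-based clustering in the mclust tradition: a grid of component counts K
and covariance structures is fitted by EM, and the model maximizing
``BIC = 2 log L - p log n`` is selected.  Six covariance families are
supported, spanning the spherical/diagonal/full x equal/varying lattice:

==================  =========================================  cov params
spherical-equal     one variance for all components/dims       1
spherical-varying   one variance per component                 K
diagonal-equal      shared diagonal covariance                 d
diagonal-varying    per-component diagonal covariance          K*d
full-shared         one full covariance for all components     d(d+1)/2
full-varying        per-component full covariance              K*d(d+1)/2
==================  =========================================  ==========

EM is initialized from k-means++ seedings (``n_init`` restarts, best final
log-likelihood kept) and applies a variance floor of 1e-6 to eigenvalues /
diagonal entries to avoid singular fits.  Cluster labels are renumbered
1..K by decreasing cluster size (ties broken by smallest original index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "STRUCTURES",
    "MixtureModel",
    "ClusterAssignment",
    "DegenerateFitError",
    "fit_gmm",
    "bic_score",
    "select_model",
    "assign",
]

STRUCTURES = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-equal",
    "diagonal-varying",
    "full-shared",
    "full-varying",
)

VAR_FLOOR = 1e-6


class DegenerateFitError(RuntimeError):
    """EM collapsed (empty component, singular covariance, or degenerate data)."""

    def __init__(self, msg: str, bic_table: pd.DataFrame | None = None):
        super().__init__(msg)
        self.bic_table = bic_table


@dataclass
class MixtureModel:
    K: int
    covariance_structure: str
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # (K, d, d), expanded regardless of structure
    log_likelihood: float
    n_params: int
    bic: float
    converged: bool = True
    n_iter: int = 0
    loglik_history: list[float] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class ClusterAssignment:
    """Hard labels (1..K, size-ordered) plus posterior responsibilities."""

    labels: pd.Series            # sample_id -> label in 1..K
    posterior: pd.DataFrame      # sample_id x label columns (1..K)

    @property
    def K(self) -> int:
        return self.posterior.shape[1]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _cov_param_count(structure: str, K: int, d: int) -> int:
    return {
        "spherical-equal": 1,
        "spherical-varying": K,
        "diagonal-equal": d,
        "diagonal-varying": K * d,
        "full-shared": d * (d + 1) // 2,
        "full-varying": K * d * (d + 1) // 2,
    }[structure]


def _floor_cov(cov: np.ndarray) -> np.ndarray:
    """Clip eigenvalues of a symmetric matrix at the variance floor."""
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= VAR_FLOOR:
        return cov
    vals = np.clip(vals, VAR_FLOOR, None)
    return (vecs * vals) @ vecs.T


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, K) matrix of component log densities."""
    n, d = X.shape
    K = means.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        sol = np.linalg.solve(L, diff.T)  # (d, n), triangular system
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def _mstep(X: np.ndarray, resp: np.ndarray, structure: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    K = resp.shape[1]
    Nk = resp.sum(axis=0)
    if Nk.min() < 1e-10:
        raise DegenerateFitError("a mixture component became empty during EM")
    weights = Nk / n
    means = (resp.T @ X) / Nk[:, None]
    covs = np.empty((K, d, d))
    if structure in ("spherical-equal", "spherical-varying", "diagonal-equal", "diagonal-varying"):
        # per-component weighted squared deviations, (K, d)
        sq = np.stack([(resp[:, k, None] * (X - means[k]) ** 2).sum(axis=0) for k in range(K)])
        if structure == "spherical-varying":
            var = sq.sum(axis=1) / (Nk * d)                      # (K,)
            diag = np.clip(var, VAR_FLOOR, None)[:, None] * np.ones(d)
        elif structure == "spherical-equal":
            var = sq.sum() / (n * d)
            diag = np.full((K, d), max(var, VAR_FLOOR))
        elif structure == "diagonal-varying":
            diag = np.clip(sq / Nk[:, None], VAR_FLOOR, None)    # (K, d)
        else:  # diagonal-equal
            diag = np.tile(np.clip(sq.sum(axis=0) / n, VAR_FLOOR, None), (K, 1))
        for k in range(K):
            covs[k] = np.diag(diag[k])
    elif structure == "full-varying":
        for k in range(K):
            diff = X - means[k]
            covs[k] = _floor_cov((resp[:, k, None] * diff).T @ diff / Nk[k])
    else:  # full-shared
        S = np.zeros((d, d))
        for k in range(K):
            diff = X - means[k]
            S += (resp[:, k, None] * diff).T @ diff
        S = _floor_cov(S / n)
        covs[:] = S
    return weights, means, covs


def fit_gmm(
    X: np.ndarray,
    K: int,
    covariance_structure: str = "full-varying",
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture by EM with k-means++ restarts.

    ``tol`` is the relative change in log-likelihood between successive EM
    iterations below which the fit is declared converged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    if n <= K:
        raise ValueError(f"need more samples than components (n={n}, K={K})")
    if covariance_structure not in STRUCTURES:
        raise ValueError(f"unknown covariance structure {covariance_structure!r}")
    if K > 1 and np.allclose(X, X[0]):
        raise DegenerateFitError("all rows identical; cannot fit K > 1 components")

    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    failures: list[str] = []
    for init in range(n_init):
        try:
            model = _fit_once(X, K, covariance_structure, rng, tol, max_iter)
        except (DegenerateFitError, np.linalg.LinAlgError) as exc:
            failures.append(str(exc))
            continue
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise DegenerateFitError(
            f"all {n_init} EM initializations degenerate: {failures[0]}"
        )
    return best


def _fit_once(X, K, structure, rng, tol, max_iter) -> MixtureModel:
    n, d = X.shape
    seed_state = int(rng.integers(0, 2**31 - 1))
    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed_state)
    # hard assignment to nearest center -> initial responsibilities
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    resp = np.zeros((n, K))
    resp[np.arange(n), d2.argmin(axis=1)] = 1.0
    resp += 1e-10
    resp /= resp.sum(axis=1, keepdims=True)

    weights, means, covs = _mstep(X, resp, structure)
    prev_ll = -np.inf
    history: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        log_dens = _log_gauss(X, means, covs) + np.log(weights)
        ll = float(logsumexp(log_dens, axis=1).sum())
        history.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
        resp = np.exp(log_dens - logsumexp(log_dens, axis=1, keepdims=True))
        weights, means, covs = _mstep(X, resp, structure)
    p = (K - 1) + K * d + _cov_param_count(structure, K, d)
    ll = history[-1]
    model = MixtureModel(
        K=K,
        covariance_structure=structure,
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=ll,
        n_params=p,
        bic=2.0 * ll - p * np.log(n),
        converged=converged,
        n_iter=len(history),
        loglik_history=history,
    )
    return model


def bic_score(model: MixtureModel, n: int) -> float:
    """BIC = 2 log L - p log n (larger is better, mclust sign convention)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 2.0 * model.log_likelihood - model.n_params * np.log(n)


def assign(model: MixtureModel, X: np.ndarray, sample_ids: list[str] | None = None) -> ClusterAssignment:
    """Posterior responsibilities and size-ordered hard labels for X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size and X.shape[1] != model.d:
        raise ValueError(f"dimension mismatch: model d={model.d}, X d={X.shape[1]}")
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if n == 0:
        return ClusterAssignment(
            labels=pd.Series([], dtype=int),
            posterior=pd.DataFrame(columns=range(1, model.K + 1)),
        )
    log_dens = _log_gauss(X, model.means, model.covariances) + np.log(model.weights)
    post = np.exp(log_dens - logsumexp(log_dens, axis=1, keepdims=True))
    raw_labels = post.argmax(axis=1)
    # renumber components 1..K by decreasing assigned size, ties -> smaller index
    counts = np.bincount(raw_labels, minlength=model.K)
    order = np.lexsort((np.arange(model.K), -counts))
    remap = np.empty(model.K, dtype=int)
    remap[order] = np.arange(1, model.K + 1)
    labels = pd.Series(remap[raw_labels], index=sample_ids, name="label")
    post_df = pd.DataFrame(post[:, order], index=sample_ids, columns=range(1, model.K + 1))
    return ClusterAssignment(labels=labels, posterior=post_df)


def select_model(
    X: np.ndarray,
    k_range: range | list[int] = range(1, 10),
    structures: tuple[str, ...] = STRUCTURES,
    seed: int = 0,
    n_init: int = 10,
    sample_ids: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[MixtureModel, ClusterAssignment, pd.DataFrame]:
    """Exhaustive (K, structure) grid search; returns the max-BIC model.

    The BIC table records every candidate, including skipped (K >= n) and
    degenerate fits, for reporting.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    rows = []
    best: MixtureModel | None = None
    for K in k_range:
        for structure in structures:
            if K >= n:
                rows.append((K, structure, np.nan, "skipped: K >= n"))
                continue
            sub_seed = (seed * 1_000_003 + K * 613 + STRUCTURES.index(structure)) % (2**31 - 1)
            try:
                model = fit_gmm(X, K, structure, seed=sub_seed, n_init=n_init,
                                tol=tol, max_iter=max_iter)
            except (DegenerateFitError, ValueError) as exc:
                rows.append((K, structure, np.nan, f"degenerate: {exc}"))
                continue
            rows.append((K, structure, model.bic, "ok"))
            if best is None or model.bic > best.bic:
                best = model
    table = pd.DataFrame(rows, columns=["K", "structure", "bic", "note"])
    if best is None:
        raise DegenerateFitError("no candidate model could be fitted", bic_table=table)
    return best, assign(best, X, sample_ids), table
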