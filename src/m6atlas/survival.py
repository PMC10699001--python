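"""From-scratch survival machinery.

Cox proportional hazards (Newton-Raphson on the partial likelihood with
Efron or Breslow tie handling and step-halving), Kaplan-Meier product-limit
curves, the K-group log-rank test, L1-penalized Cox regression fitted by
IRLS + coordinate descent along a warm-started lambda path with k-fold
cross-validated partial-likelihood deviance, median-split risk groups, and
time-dependent cumulative/dynamic AUC with inverse-probability-of-censoring
(IPCW) weights.

Rank-based helpers (Kruskal-Wallis, chi-square, Spearman) wrap scipy behind
the same module surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "CoxFit",
    "KMCurve",
    "LassoCoxPath",
    "RiskModel",
    "cox_fit",
    "univariate_screen",
    "km_estimate",
    "logrank_test",
    "lasso_cox",
    "risk_model",
    "td_auc",
    "kruskal_wallis",
    "chi_square",
    "spearman",
]

BETA_CAP = 20.0


@dataclass
class CoxFit:
    coefficients: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    log_partial_likelihood: float
    ties_method: str
    converged: bool
    n_iter: int

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


@dataclass
class KMCurve:
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) at each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t) — right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LassoCoxPath:
    lambdas: np.ndarray
    coefs: pd.DataFrame              # genes x lambdas, original scale
    cv_mean: np.ndarray | None
    cv_se: np.ndarray | None
    selected_lambda: float
    selected_index: int
    train_deviance: np.ndarray = field(default=None)

    @property
    def active_genes(self) -> list[str]:
        col = self.coefs.iloc[:, self.selected_index]
        return list(col.index[col != 0.0])

    def selected_coefficients(self) -> pd.Series:
        col = self.coefs.iloc[:, self.selected_index]
        return col[col != 0.0]


@dataclass
class RiskModel:
    genes: list[str]
    coefficients: pd.Series
    scores: pd.Series
    groups: pd.Series                # "High" / "Low"
    cutpoint: float
    td_auc: dict[int, float]


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron / Breslow)
# ---------------------------------------------------------------------------

def _prepare(time: np.ndarray, event: np.ndarray, Z: np.ndarray):
    order = np.argsort(time, kind="stable")
    return time[order], event[order].astype(bool), Z[order]


def cox_loglik(beta: np.ndarray, time: np.ndarray, event: np.ndarray, Z: np.ndarray,
               ties: str = "efron", derivatives: bool = True):
    """Log partial likelihood and (optionally) its gradient and Hessian.

    Risk-set sums are taken from suffix cumulative sums over the
    time-sorted sample, so one evaluation costs O(n p^2).
    """
    time, event, Z = _prepare(np.asarray(time, float), np.asarray(event), np.asarray(Z, float))
    n, p = Z.shape
    eta = Z @ beta
    w = np.exp(eta)
    wZ = w[:, None] * Z
    wZZ = wZ[:, :, None] * Z[:, None, :]
    # suffix sums: S*[i] aggregates subjects with time >= time[i]
    S0s = np.cumsum(w[::-1])[::-1]
    S1s = np.cumsum(wZ[::-1], axis=0)[::-1]
    S2s = np.cumsum(wZZ[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    event_times = np.unique(time[event])
    eidx = np.flatnonzero(event)
    if len(event_times) == len(eidx):
        # no tied event times: fully vectorized (Efron == Breslow here)
        lo = np.searchsorted(time, time[eidx], side="left")
        S0 = S0s[lo]
        S1 = S1s[lo]
        ll = float(eta[eidx].sum() - np.log(S0).sum())
        if not derivatives:
            return ll
        m = S1 / S0[:, None]
        grad = (Z[eidx] - m).sum(axis=0)
        hess = -(S2s[lo] / S0[:, None, None] - m[:, :, None] * m[:, None, :]).sum(axis=0)
        return ll, grad, hess
    for t in event_times:
        lo = np.searchsorted(time, t, side="left")
        hi = np.searchsorted(time, t, side="right")
        dead = np.flatnonzero(event[lo:hi]) + lo
        d = len(dead)
        S0, S1, S2 = S0s[lo], S1s[lo], S2s[lo]
        s0d = w[dead].sum()
        s1d = wZ[dead].sum(axis=0)
        s2d = wZZ[dead].sum(axis=0)
        ll += eta[dead].sum()
        if derivatives:
            grad += Z[dead].sum(axis=0)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            a0 = S0 - frac * s0d
            a1 = S1 - frac * s1d
            a2 = S2 - frac * s2d
            ll -= np.log(a0)
            if derivatives:
                m = a1 / a0
                grad -= m
                hess -= a2 / a0 - np.outer(m, m)
    if not derivatives:
        return ll
    return ll, grad, hess


def cox_fit(
    clinical: ClinicalTable | pd.DataFrame,
    covariates: pd.DataFrame | list[str],
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Newton-Raphson Cox PH fit with step-halving.

    ``covariates`` may be a numeric DataFrame indexed by sample id or a list
    of column names drawn from the clinical table itself.  Fits that run
    toward monotone likelihood (separation) are returned flagged
    ``converged=False`` with |beta| capped.
    """
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    if isinstance(covariates, list):
        cov = data[covariates].copy()
    else:
        cov = covariates.reindex(data.index)
    if cov.isna().any().any():
        raise ValueError("covariates missing for some samples")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    time = data["os_time"].to_numpy(float)
    event = data["os_event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    const = cov.columns[cov.nunique() <= 1]
    if len(const):
        raise ValueError(f"constant covariate: {const[0]}")
    Z = cov.to_numpy(float)
    names = list(cov.columns)
    p = Z.shape[1]

    beta = np.zeros(p)
    ll, grad, hess = cox_loglik(beta, time, event, Z, ties)
    converged = False
    it = 0
    capped = False
    # convergence: gradient norm below tol relative to the likelihood scale
    def _small(g, cur_ll):
        return np.linalg.norm(g) < tol * (1.0 + abs(cur_ll))

    for it in range(1, max_iter + 1):
        if _small(grad, ll):
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll = cox_loglik(new_beta, time, event, Z, ties, derivatives=False)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = cox_loglik(new_beta, time, event, Z, ties, derivatives=False)
            halvings += 1
        if new_ll < ll:
            # no ascent possible: at the numerical optimum
            converged = _small(grad, ll)
            break
        beta = new_beta
        if np.abs(beta).max() > BETA_CAP:
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            capped = True
        ll, grad, hess = cox_loglik(beta, time, event, Z, ties)
        if capped:
            warnings.warn("Cox fit appears separated; coefficients capped", RuntimeWarning)
            break
        if _small(grad, ll):
            converged = True
            break
    cov_mat = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov_mat), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return CoxFit(
        coefficients=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        z=pd.Series(z, index=idx),
        p=pd.Series(pvals, index=idx),
        log_partial_likelihood=float(ll),
        ties_method=ties,
        converged=converged and not capped,
        n_iter=it,
    )


def univariate_screen(
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-gene univariate Cox screen; keeps genes with Wald p < alpha (strict).

    Per-gene failures become NA rows with a reason instead of aborting.
    """
    genes = [g.upper() for g in (genes or X.gene_ids)]
    shared = [s for s in X.sample_ids if s in clinical.data.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared between expression and clinical")
    clin = ClinicalTable(clinical.data.loc[shared])
    rows = []
    for g in genes:
        expr = X.values.loc[g, shared]
        cov = pd.DataFrame({g: expr.to_numpy()}, index=shared)
        try:
            fit = cox_fit(clin, cov)
            rows.append((g, fit.coefficients.iloc[0], float(np.exp(fit.coefficients.iloc[0])),
                         fit.se.iloc[0], fit.p.iloc[0], ""))
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, str(exc)))
    table = pd.DataFrame(rows, columns=["gene", "coef", "hr", "se", "p", "note"]).set_index("gene")
    significant = set(table.index[table["p"] < alpha])
    return table, significant


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def _km(time: np.ndarray, event: np.ndarray) -> KMCurve:
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order].astype(bool)
    uniq = np.unique(time[event])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in uniq:
        n_t = int((time >= t).sum())
        d_t = int((event & (time == t)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
        n_ev.append(d_t)
    return KMCurve(
        times=uniq,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        n_events=np.array(n_ev),
        censor_times=np.sort(time[~event]),
    )


def km_estimate(
    clinical: ClinicalTable | pd.DataFrame,
    group_labels: pd.Series | None = None,
) -> dict[str, KMCurve]:
    """Product-limit survival curves, one per group (single group "all" if None)."""
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    time = data["os_time"].to_numpy(float)
    event = data["os_event"].to_numpy(int)
    if group_labels is None:
        return {"all": _km(time, event)}
    lab = group_labels.reindex(data.index)
    if lab.isna().any():
        missing = lab.index[lab.isna()][0]
        raise ValueError(f"no group label for sample {missing!r}")
    out = {}
    for g in sorted(lab.unique(), key=str):
        mask = (lab == g).to_numpy()
        out[str(g)] = _km(time[mask], event[mask])
    return out


def logrank_test(
    clinical: ClinicalTable | pd.DataFrame,
    group_labels: pd.Series,
) -> tuple[float, int, float]:
    """K-group log-rank test: (chi2, df, p) with df = K - 1."""
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    lab = group_labels.reindex(data.index)
    if lab.isna().any():
        raise ValueError("group labels missing for some samples")
    groups = sorted(lab.unique(), key=str)
    K = len(groups)
    if K < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    time = data["os_time"].to_numpy(float)
    event = data["os_event"].to_numpy(bool)
    if event.sum() == 0:
        raise ValueError("no events")
    gidx = np.array([groups.index(g) for g in lab])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for t in np.unique(time[event]):
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = (event & (time == t)).sum()
        n_k = np.array([(at_risk & (gidx == k)).sum() for k in range(K)], float)
        d_k = np.array([((event) & (time == t) & (gidx == k)).sum() for k in range(K)], float)
        O += d_k
        E += d_t * n_k / n_t
        if n_t > 1:
            frac = n_k / n_t
            V += d_t * (n_t - d_t) / (n_t - 1) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff) if np.any(Vsub) else 0.0
    df = K - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# Lasso-Cox (Breslow ties, IRLS + coordinate descent)
# ---------------------------------------------------------------------------

def _cox_eta_derivs(eta, time, event):
    """Breslow gradient u and diagonal Hessian w of lpl w.r.t. eta."""
    n = len(eta)
    w_exp = np.exp(eta)
    u = event.astype(float).copy()
    h = np.zeros(n)       # cumulative d_t / S_t over event times <= t_i
    h2 = np.zeros(n)      # cumulative d_t / S_t^2
    for t in np.unique(time[event.astype(bool)]):
        risk = time >= t
        d_t = float((event.astype(bool) & (time == t)).sum())
        S = w_exp[risk].sum()
        h[risk] += d_t / S
        h2[risk] += d_t / S**2
    u -= w_exp * h
    wdiag = w_exp * h - (w_exp**2) * h2
    return u, np.maximum(wdiag, 1e-10)


def _breslow_lpl(eta, time, event):
    ll = eta[event.astype(bool)].sum()
    w_exp = np.exp(eta)
    for t in np.unique(time[event.astype(bool)]):
        d_t = float((event.astype(bool) & (time == t)).sum())
        ll -= d_t * np.log(w_exp[time >= t].sum())
    return float(ll)


def _cd_weighted_lasso(Xs, z, w, lam, beta, max_sweeps=100, tol=1e-7):
    """Coordinate descent for 1/(2n) sum w (z - X b)^2 + lam |b|_1.

    Full sweeps alternate with active-set sweeps over the current support
    (the usual glmnet strategy).
    """
    n, p = Xs.shape
    r = z - Xs @ beta
    wX = w[:, None] * Xs
    denom = (wX * Xs).sum(axis=0) / n

    def sweep(indices):
        nonlocal r
        max_delta = 0.0
        for j in indices:
            if denom[j] <= 0:
                continue
            rho = wX[:, j] @ r / n + beta[j] * denom[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom[j]
            delta = new - beta[j]
            if delta != 0.0:
                r -= Xs[:, j] * delta
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        return max_delta

    all_idx = np.arange(p)
    for _ in range(max_sweeps):
        if sweep(all_idx) < tol:
            break
        active = np.flatnonzero(beta)
        for _ in range(max_sweeps):
            if len(active) == 0 or sweep(active) < tol:
                break
    return beta


def _penalized_cox(Xs, time, event, lam, beta0, outer_max=50, tol=1e-7):
    """One penalized Breslow-Cox fit at a fixed lambda (standardized X)."""
    if lam == 0.0:
        # unpenalized endpoint: run IRLS to full Newton accuracy
        outer_max, tol = 200, 1e-12
    n = Xs.shape[0]
    beta = beta0.copy()
    prev_obj = np.inf
    for _ in range(outer_max):
        eta = Xs @ beta
        u, w = _cox_eta_derivs(eta, time, event)
        z = eta + u / w
        beta = _cd_weighted_lasso(Xs, z, w, lam, beta)
        obj = -_breslow_lpl(Xs @ beta, time, event) / n + lam * np.abs(beta).sum()
        if abs(prev_obj - obj) < tol * (abs(prev_obj) + 1e-12):
            break
        prev_obj = obj
    return beta


def lasso_cox(
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.05,
) -> LassoCoxPath:
    """L1-penalized Cox path with k-fold CV-deviance lambda selection.

    The grid runs from lambda_max (smallest penalty with an all-zero
    solution) down ``n_lambda`` log-spaced points; folds are seeded and
    stratified by event status; the selected lambda minimizes the mean
    cross-validated partial-likelihood deviance.
    """
    genes = [g.upper() for g in (genes or X.gene_ids)]
    if len(genes) < 2:
        raise ValueError("need at least 2 candidate genes")
    shared = [s for s in X.sample_ids if s in clinical.data.index]
    data = clinical.data.loc[shared]
    time = data["os_time"].to_numpy(float)
    event = data["os_event"].to_numpy(int)
    n_events = int(event.sum())
    if lambda_grid is None and n_events < n_folds:
        raise ValueError(
            f"only {n_events} events for {n_folds} folds; reduce n_folds"
        )
    Xmat = X.values.loc[genes, shared].to_numpy(float).T  # samples x genes
    mu = Xmat.mean(axis=0)
    sd = Xmat.std(axis=0)
    keep = sd > 0
    if not keep.all():
        genes = [g for g, k in zip(genes, keep) if k]
        Xmat, mu, sd = Xmat[:, keep], mu[keep], sd[keep]
    Xs = (Xmat - mu) / sd
    n, p = Xs.shape

    u0, _ = _cox_eta_derivs(np.zeros(n), time, event)
    lam_max = float(np.abs(Xs.T @ u0).max() / n)
    if lambda_grid is None:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
        run_cv = True
    else:
        lambdas = np.asarray(lambda_grid, float)
        run_cv = False

    def fit_path(Xs_, time_, event_):
        betas = np.zeros((p, len(lambdas)))
        b = np.zeros(p)
        for i, lam in enumerate(lambdas):
            b = _penalized_cox(Xs_, time_, event_, lam, b)
            betas[:, i] = b
        return betas

    betas = fit_path(Xs, time, event)
    train_dev = np.array(
        [-2.0 * _breslow_lpl(Xs @ betas[:, i], time, event) for i in range(len(lambdas))]
    )

    cv_mean = cv_se = None
    sel = len(lambdas) - 1
    if run_cv:
        rng = np.random.default_rng(seed)
        folds = np.empty(n, dtype=int)
        for status in (0, 1):
            idx = np.flatnonzero(event == status)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
        dev = np.zeros((n_folds, len(lambdas)))
        for f in range(n_folds):
            tr = folds != f
            b_tr = fit_path(Xs[tr], time[tr], event[tr])
            for i in range(len(lambdas)):
                eta_all = Xs @ b_tr[:, i]
                # V&VH cross-validated deviance: full minus train
                dev[f, i] = -2.0 * (
                    _breslow_lpl(eta_all, time, event)
                    - _breslow_lpl(eta_all[tr], time[tr], event[tr])
                )
        cv_mean = dev.mean(axis=0)
        cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        sel = int(np.argmin(cv_mean))

    coefs = pd.DataFrame(betas / sd[:, None], index=genes, columns=lambdas)
    return LassoCoxPath(
        lambdas=lambdas,
        coefs=coefs,
        cv_mean=cv_mean,
        cv_se=cv_se,
        selected_lambda=float(lambdas[sel]),
        selected_index=sel,
        train_deviance=train_dev,
    )


# ---------------------------------------------------------------------------
# Risk model and time-dependent AUC
# ---------------------------------------------------------------------------

def td_auc(scores: np.ndarray, time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """IPCW cumulative/dynamic AUC at the given horizon.

    Cases are subjects with an event by the horizon, controls those still
    under observation beyond it; case weights are 1/G(t-) with G the
    Kaplan-Meier estimate of the censoring distribution.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if horizon > time.max():
        raise ValueError(f"horizon {horizon} exceeds last follow-up time {time.max()}")
    cens_km = _km(time, 1 - event)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("tdAUC undefined: no cases or no controls at horizon")
    wts = np.array([1.0 / max(cens_km.at(t - 1e-9), 1e-12) for t in time[cases]])
    sc = scores[cases]
    sj = scores[controls]
    conc = (sc[:, None] > sj[None, :]).astype(float) + 0.5 * (sc[:, None] == sj[None, :])
    num = (wts[:, None] * conc).sum()
    den = wts.sum() * len(sj)
    return float(num / den)


def risk_model(
    path: LassoCoxPath,
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    horizons: list[int] = (365, 730, 1095),
) -> RiskModel:
    """Linear risk score from the selected lasso fit; High/Low by median split."""
    coef = path.selected_coefficients()
    if coef.empty:
        raise ValueError("no prognostic genes at selected lambda")
    shared = [s for s in X.sample_ids if s in clinical.data.index]
    expr = X.values.loc[list(coef.index), shared]
    scores = pd.Series(coef.to_numpy() @ expr.to_numpy(), index=shared, name="risk_score")
    cut = float(scores.median())
    groups = pd.Series(np.where(scores > cut, "High", "Low"), index=shared, name="risk_group")
    data = clinical.data.loc[shared]
    aucs = {
        int(h): td_auc(scores.to_numpy(), data["os_time"].to_numpy(), data["os_event"].to_numpy(), h)
        for h in horizons
    }
    return RiskModel(
        genes=list(coef.index),
        coefficients=coef,
        scores=scores,
        groups=groups,
        cutpoint=cut,
        td_auc=aucs,
    )


# ---------------------------------------------------------------------------
# Rank / contingency helpers
# ---------------------------------------------------------------------------

def kruskal_wallis(values: np.ndarray, group_labels: np.ndarray) -> tuple[float, int, float]:
    """Kruskal-Wallis H test: (H, df, p); H = 0, p = 1 when all values tie."""
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if np.allclose(values, values[0]):
        return 0.0, len(groups) - 1, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), len(groups) - 1, float(p)


def chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative cell count")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
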