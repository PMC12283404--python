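"""Regression layer: log-OLS, quasi-Poisson GLM and Pagel's-lambda PGLS.

The phylogenetic model: under Brownian motion the expected covariance of a
trait between species i and j is proportional to the shared root-to-MRCA
path length C[i, j]. Pagel's lambda scales the off-diagonal entries of C,
interpolating between phylogenetic independence (lambda = 0) and the full
Brownian structure (lambda = 1); it is estimated by profile maximum
likelihood over [0, 1]. Generalized least squares with the resulting
covariance corrects the error structure of the regression of log range
size on lifeform.

Effect sizes are reported as percentage differences, 100*(exp(beta) - 1),
with Wald 95% confidence intervals on the log scale. Fits across a set of
trees (differing in the placement of imputed taxa) are aggregated as the
coefficient-wise mean and between-tree standard deviation.

All solves go through symmetric (Cholesky) factorizations of the
covariance matrix; an explicit inverse of V is never formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

__all__ = [
    "Z95",
    "MAX_VCV_TAXA",
    "RegressionFit",
    "EffectSize",
    "MultiTreeSummary",
    "phylo_vcv",
    "lambda_transform",
    "gls_fit",
    "pgls_ml",
    "ols_log",
    "quasipoisson_glm",
    "effect_size_percent",
    "aggregate_trees",
]

#: Two-sided 95% normal quantile used for Wald intervals.
Z95 = 1.959964

#: Dense-covariance cap: phylogenetic GLS holds an n x n matrix, so memory
#: is O(n^2). Beyond this, prune the tree / subset the species first.
MAX_VCV_TAXA = 20_000


@dataclass
class RegressionFit:
    """Coefficients and inference for one fitted model.

    ``lambda_hat`` is set for PGLS fits, ``dispersion_phi`` for
    quasi-Poisson fits; ``loglik`` is absent for quasi-likelihood models.
    """

    model: str
    beta: np.ndarray
    se: np.ndarray
    n_obs: int
    residual_df: int
    lambda_hat: float | None = None
    dispersion_phi: float | None = None
    loglik: float | None = None
    coef_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.beta.shape != self.se.shape:
            raise ValueError("beta and se must have the same length")
        if self.n_obs <= self.beta.size:
            raise ValueError("need more observations than coefficients")


@dataclass(frozen=True)
class EffectSize:
    """Percentage difference relative to the reference class, with 95% CI."""

    percent: float
    ci_low: float
    ci_high: float
    coef_index: int


@dataclass
class MultiTreeSummary:
    """Coefficient-wise mean and between-tree spread over a set of tree fits.

    ``spread`` is the standard deviation of the tree-wise estimates (the
    between-tree variability itself, not divided by sqrt(n_trees));
    ``se_mean`` is the mean within-fit standard error, for comparison.
    """

    model: str
    n_trees: int
    beta_mean: np.ndarray
    beta_spread: np.ndarray
    se_mean: np.ndarray
    lambda_hats: np.ndarray
    coef_names: tuple[str, ...] | None = None


def _node_depths(tree: dendropy.Tree) -> dict:
    depths: dict = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
            continue
        el = nd.edge.length
        if el is None:
            raise ValueError("edge without branch length; covariances undefined")
        if el < 0:
            raise ValueError("negative branch length")
        depths[nd] = depths[nd.parent_node] + el
    return depths


def phylo_vcv(tree: dendropy.Tree, taxa, *, max_taxa: int = MAX_VCV_TAXA) -> np.ndarray:
    """Brownian-motion variance-covariance matrix of a tree.

    ``C[i, j]`` is the shared root-to-MRCA path length of taxa i and j
    (root depth 0); ``C[i, i]`` is the root-to-tip path length. Rows and
    columns follow the order of ``taxa``; tips of the tree not listed in
    ``taxa`` are ignored.
    """
    taxa = list(taxa)
    n = len(taxa)
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds the dense-covariance cap of {max_taxa}; "
            "prune the tree or subset the species"
        )
    index = {t: i for i, t in enumerate(taxa)}
    if len(index) != n:
        raise ValueError("duplicate taxa")
    depths = _node_depths(tree)
    tip_label = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            tip_label[leaf] = leaf.taxon.label
    found = {tip_label[l] for l in tip_label if tip_label[l] in index}
    missing = sorted(set(taxa) - found)
    if missing:
        raise ValueError(f"taxa not found in tree: {missing}")

    C = np.zeros((n, n))
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index.get(tip_label.get(nd))
            if i is not None:
                C[i, i] = depths[nd]
                below[nd] = [i]
            else:
                below[nd] = []
            continue
        child_sets = [below.pop(ch) for ch in nd.child_nodes()]
        d = depths[nd]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = d
                        C[j, i] = d
        below[nd] = [i for s in child_sets for i in s]
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal entries of C by Pagel's lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    return V


def gls_fit(y, X, V, *, model: str = "gls",
            coef_names: tuple[str, ...] | None = None) -> RegressionFit:
    """Generalized least squares with known covariance structure V.

    ``beta = (X' V^-1 X)^-1 X' V^-1 y``, solved via a Cholesky
    factorization of V. The reported log-likelihood uses the ML variance
    ``e' V^-1 e / n``; standard errors use the ``n - p`` denominator.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    V = np.asarray(V, dtype=float)
    try:
        cho = sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise ValueError(f"covariance matrix V is not positive definite: {exc}")
    except sla.LinAlgError as exc:
        raise ValueError(f"covariance matrix V is not positive definite: {exc}")
    Vi_y = sla.cho_solve(cho, y)
    Vi_X = sla.cho_solve(cho, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    e = y - X @ beta
    q = float(e @ sla.cho_solve(cho, e))
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    sigma2_ml = q / n
    if sigma2_ml <= 0:
        sigma2_ml = np.finfo(float).tiny
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdetV + n)
    cov_beta = (q / (n - p)) * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    return RegressionFit(
        model=model, beta=beta, se=se, n_obs=n, residual_df=n - p,
        loglik=loglik, coef_names=coef_names,
    )


def ols_log(y_raw, X, *, coef_names: tuple[str, ...] | None = None) -> RegressionFit:
    """OLS of ln(y_raw) on X (log-transformed response, classical SEs)."""
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    bad = np.flatnonzero(y_raw <= 0)
    if bad.size:
        raise ValueError(
            f"log-transform requires positive responses; offending indices: {bad.tolist()}"
        )
    y = np.log(y_raw)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    e = y - X @ beta
    rss = float(e @ e)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    s2_ml = max(rss / n, np.finfo(float).tiny)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * s2_ml) + 1.0)
    return RegressionFit(
        model="ols_log", beta=beta, se=se, n_obs=n, residual_df=n - p,
        loglik=loglik, coef_names=coef_names,
    )


def pgls_ml(y, X, tree: dendropy.Tree, taxa, *, lam: float | None = None,
            xatol: float = 1e-6,
            coef_names: tuple[str, ...] | None = None) -> RegressionFit:
    """PGLS with Pagel's lambda estimated by profile maximum likelihood.

    The profile log-likelihood over lambda is maximized on [0, 1] by
    bounded scalar optimization; both endpoints are evaluated explicitly
    so boundary optima are exact. Pass ``lam`` to fix lambda instead of
    estimating it.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    C = phylo_vcv(tree, taxa)
    if np.max(np.diag(C)) <= 0:
        raise ValueError("zero-length tree: likelihood undefined")

    def fit_at(l: float) -> RegressionFit:
        return gls_fit(y, X, lambda_transform(C, l), model="pgls",
                       coef_names=coef_names)

    if lam is not None:
        fit = fit_at(lam)
        fit.lambda_hat = float(lam)
        return fit

    def nll(l: float) -> float:
        try:
            return -fit_at(float(l)).loglik
        except ValueError:
            return np.inf

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": xatol})
    candidates = [0.0, 1.0, float(res.x)]
    values = [nll(l) for l in candidates]
    best = candidates[int(np.argmin(values))]
    if not np.isfinite(min(values)):
        raise ValueError("non-finite profile likelihood (degenerate tree or data)")
    fit = fit_at(best)
    fit.lambda_hat = best
    return fit


def quasipoisson_glm(y_counts, X, *, tol: float = 1e-10, max_iter: int = 100,
                     coef_names: tuple[str, ...] | None = None) -> RegressionFit:
    """Log-link quasi-Poisson regression via IRLS.

    The mean model is the Poisson score equation; the dispersion
    ``phi = sum(Pearson residual^2) / (n - p)`` scales the Poisson
    standard errors by sqrt(phi) to account for over- (or under-)
    dispersion.
    """
    y = np.asarray(y_counts, dtype=float).ravel()
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y_counts must be nonnegative integers")
    if not np.any(y > 0):
        raise ValueError("all counts are zero; model undefined")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    # Indicator column whose group has all-zero counts => estimate -> -inf.
    for j in range(p):
        col = X[:, j]
        uniq = np.unique(col)
        if set(uniq.tolist()) <= {0.0, 1.0} and 0.0 in uniq and 1.0 in uniq:
            if y[col == 1.0].sum() == 0:
                raise ValueError(
                    f"column {j}: group indicated has all-zero counts "
                    "(infinite estimate)"
                )
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros(p)
    trace = []
    converged = False
    for _ in range(max_iter):
        W = mu
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        XtWX = X.T @ WX
        beta_new = np.linalg.solve(XtWX, WX.T @ z)
        trace.append(beta_new.copy())
        step = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        beta = beta_new
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        if step <= tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            "IRLS failed to converge in "
            f"{max_iter} iterations; trace tail: {[t.round(6).tolist() for t in trace[-3:]]}"
        )
    W = mu
    XtWX = X.T @ (X * W[:, None])
    phi = float(np.sum((y - mu) ** 2 / mu) / (n - p))
    if phi == 0.0:
        warnings.warn("zero Pearson dispersion (degenerate fit)", RuntimeWarning)
    se = np.sqrt(np.maximum(phi, 0.0) * np.diag(np.linalg.inv(XtWX)))
    return RegressionFit(
        model="quasipoisson", beta=beta, se=se, n_obs=n, residual_df=n - p,
        dispersion_phi=phi, coef_names=coef_names,
    )


def effect_size_percent(fit: RegressionFit, k: int) -> EffectSize:
    """Percentage difference 100*(exp(beta_k) - 1) with Wald 95% CI.

    Only meaningful for models with a log link or log-transformed
    response, where exp(beta) is a multiplicative effect.
    """
    if not 0 <= k < fit.beta.size:
        raise ValueError(f"coefficient index {k} out of range")
    b, s = float(fit.beta[k]), float(fit.se[k])
    return EffectSize(
        percent=100.0 * (math.exp(b) - 1.0),
        ci_low=100.0 * (math.exp(b - Z95 * s) - 1.0),
        ci_high=100.0 * (math.exp(b + Z95 * s) - 1.0),
        coef_index=k,
    )


def aggregate_trees(fits) -> MultiTreeSummary:
    """Aggregate per-tree fits: coefficient-wise mean and between-tree SD.

    All fits must share model and design; the per-tree lambda estimates
    are retained for reporting.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to aggregate")
    models = {f.model for f in fits}
    sizes = {f.beta.size for f in fits}
    if len(models) > 1 or len(sizes) > 1:
        raise ValueError(f"heterogeneous fits: models={models}, sizes={sizes}")
    B = np.vstack([f.beta for f in fits])
    S = np.vstack([f.se for f in fits])
    spread = B.std(axis=0, ddof=1) if len(fits) > 1 else np.zeros(B.shape[1])
    lams = np.array(
        [f.lambda_hat if f.lambda_hat is not None else np.nan for f in fits]
    )
    return MultiTreeSummary(
        model=fits[0].model,
        n_trees=len(fits),
        beta_mean=B.mean(axis=0),
        beta_spread=spread,
        se_mean=S.mean(axis=0),
        lambda_hats=lams,
        coef_names=fits[0].coef_names,
    )
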