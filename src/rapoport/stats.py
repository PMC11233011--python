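"""Cross-species and assemblage regression machinery.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore):

* :class:`OLS` — ordinary least squares with Gaussian ML log-likelihood
  and small-sample AICc.
* :class:`PGLS` — generalized least squares under a phylogenetic error
  covariance ``V(λ) = λ·C + (1−λ)·diag(C)`` with Pagel's λ profiled by
  maximum likelihood on [0, 1].
* :class:`SARError` — simultaneous autoregressive error model
  ``y = Xβ + u, u = ρWu + ε`` with ρ estimated by ML using the
  eigenvalue form of the log-determinant.

Module-level helpers cover standardization, variance inflation factors,
phylogenetic signal (Blomberg's K permutation test and the Pagel-λ
likelihood-ratio test), neighbourhood weight matrices, AICc all-subsets
multimodel inference with 95%-weight full averaging, and the
OLS-versus-SAR model choice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.stats import chi2
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    CombinatorialLimitError,
    ConvergenceError,
    DegenerateInputError,
    InvalidTreeError,
    LabelsMismatchError,
    RankDeficiencyError,
)
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "zscore",
    "vif",
    "OLS",
    "PGLS",
    "SARError",
    "fit_ols",
    "fit_pgls",
    "fit_sar_error",
    "SignalResult",
    "blomberg_k",
    "pagel_lambda_signal",
    "phylogenetic_signal",
    "SpatialWeights",
    "build_spatial_weights",
    "ModelSet",
    "multimodel_inference",
    "select_spatial_model",
]


# -------------------------------------------------------------- elementary ops
def zscore(values) -> np.ndarray:
    """Standardize to mean 0, variance 1 (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1-D vector")
    if np.unique(x).size < 2:
        raise DegenerateInputError("constant vector cannot be standardized")
    return (x - x.mean()) / x.std(ddof=1)


def vif(design) -> np.ndarray:
    """Variance inflation factor of each predictor: 1/(1−R²_j) from the
    regression of column j on the remaining columns (with intercept).
    Exactly collinear columns come back as +inf rather than raising."""
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    n, p = X.shape
    if p < 2 or n <= p:
        raise ValueError("vif needs n > p >= 2")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        rss = (resid**2).sum()
        if tss == 0 or rss / max(tss, np.finfo(float).tiny) < 1e-12:
            out[j] = np.inf
        else:
            out[j] = tss / rss
    return out


def _check_design(X, n) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    return X


def _rank_check(Z: np.ndarray) -> None:
    """Raise naming the offending columns if Z is rank deficient."""
    rank = np.linalg.matrix_rank(Z)
    if rank == Z.shape[1]:
        return
    bad = []
    kept: list[int] = []
    for j in range(Z.shape[1]):
        trial = Z[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            bad.append(j)
    raise RankDeficiencyError(
        f"design matrix is singular; dependent columns (0-based, incl. "
        f"intercept column 0): {bad}",
        columns=bad,
    )


def _wald_pvalues(Z: np.ndarray, rss: float, beta: np.ndarray):
    """Slope standard errors and two-sided t-test p-values (intercept
    excluded) from a (possibly transformed) design matrix."""
    n, q = Z.shape
    df = n - q
    if df <= 0:
        return np.full(q - 1, np.nan), np.full(q - 1, np.nan)
    sigma2 = rss / df
    cov = sigma2 * np.linalg.pinv(Z.T @ Z)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[1:] / se
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(np.abs(tstat), df)
    return se, p


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss, np.finfo(float).tiny) / n
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _aic_aicc(loglik: float, k: int, n: int) -> tuple[float, float]:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 > 0:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    else:
        aicc = np.inf
    return aic, aicc


# ------------------------------------------------------------------------ OLS
class OLS(RegressorMixin, BaseEstimator):
    """Ordinary least squares with ML log-likelihood and AICc.

    The parameter count for information criteria is k = p + 2
    (slopes + intercept + residual variance).
    """

    model_tag = "OLS"

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        X = _check_design(X, n)
        p = X.shape[1]
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 (n={n}, p={p})")
        Z = np.column_stack([np.ones(n), X])
        _rank_check(Z)
        beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.resid_ = resid
        self.r2_ = 1.0 - rss / tss if tss > 0 else 1.0
        self.loglik_ = _gaussian_loglik(rss, n)
        self.k_params_ = p + 2
        self.aic_, self.aicc_ = _aic_aicc(self.loglik_, self.k_params_, n)
        self.n_obs_ = n
        self.rss_ = rss
        self.se_, self.pvalues_ = _wald_pvalues(Z, rss, beta)
        return self

    def predict(self, X):
        X = _check_design(X, np.asarray(X).shape[0])
        return self.intercept_ + X @ self.coef_


def fit_ols(y, X) -> OLS:
    """Functional wrapper over :class:`OLS`."""
    return OLS().fit(X, y)


# ----------------------------------------------------------------------- PGLS
def _phylo_cov(tree: Phylogeny, labels) -> np.ndarray:
    C, _ = tree.brownian_covariance(order=labels)
    # PSD sanity: Cholesky with a tiny relative jitter
    try:
        cholesky(C + 1e-12 * np.trace(C) / len(labels) * np.eye(len(labels)),
                 lower=True)
    except np.linalg.LinAlgError as exc:
        raise InvalidTreeError("Brownian covariance is not PSD") from exc
    return C


def _match_labels(tree: Phylogeny, species) -> list[str]:
    labels = list(species)
    tips = set(tree.tip_labels)
    missing_in_tree = [s for s in labels if s not in tips]
    missing_in_data = sorted(tips - set(labels))
    if missing_in_tree or missing_in_data:
        raise LabelsMismatchError(
            f"tip/row mismatch: {len(missing_in_tree)} rows absent from tree "
            f"{missing_in_tree[:5]}, {len(missing_in_data)} tips absent from "
            f"data {missing_in_data[:5]}",
            missing_in_tree=missing_in_tree,
            missing_in_data=missing_in_data,
        )
    return labels


def _gls_profile(y: np.ndarray, Z: np.ndarray, V: np.ndarray):
    """GLS under covariance V: returns (beta, quad_resid, loglik)."""
    n = y.size
    L = cholesky(V, lower=True)
    ys = solve_triangular(L, y, lower=True)
    Zs = solve_triangular(L, Z, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Zs, ys, rcond=None)
    resid = ys - Zs @ beta
    quad = float(resid @ resid)
    sigma2 = max(quad, np.finfo(float).tiny) / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return beta, quad, loglik


class PGLS(RegressorMixin, BaseEstimator):
    """Phylogenetic generalized least squares with Pagel's λ.

    Parameters
    ----------
    tree : Phylogeny
        Rooted tree whose tips cover the observations.
    lam : "ML" or float in [0, 1]
        Profile-maximize λ ("ML") or fix it.

    ``fit(X, y, species=...)`` matches rows to tips by label; with
    ``species=None`` the rows are taken to be in ``tree.tip_labels``
    order.  λ = 0 reduces exactly to OLS.
    """

    model_tag = "PGLS"

    def __init__(self, tree=None, lam="ML"):
        self.tree = tree
        self.lam = lam

    def fit(self, X, y, species=None):
        if self.tree is None:
            raise ValueError("PGLS requires a tree")
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if n < 4:
            raise ValueError("PGLS needs at least 4 observations")
        X = _check_design(X, n)
        labels = _match_labels(
            self.tree, species if species is not None else self.tree.tip_labels
        )
        if len(labels) != n:
            raise LabelsMismatchError(
                f"{len(labels)} labels for {n} observations"
            )
        C = _phylo_cov(self.tree, labels)
        D = np.diag(np.diag(C))
        Z = np.column_stack([np.ones(n), X])
        _rank_check(Z)
        jitter = 1e-10 * np.trace(C) / n * np.eye(n)

        def V_of(lam):
            return lam * C + (1.0 - lam) * D + jitter

        def negll(lam):
            return -_gls_profile(y, Z, V_of(lam))[2]

        if self.lam == "ML":
            res = minimize_scalar(
                negll, bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-6},
            )
            cands = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, res.x)]
            _, lam_hat = min(cands, key=lambda t: t[0])
            lam_hat = float(lam_hat)
            k_extra = 1
        else:
            lam_hat = float(self.lam)
            if not 0.0 <= lam_hat <= 1.0:
                raise ValueError("lambda must lie in [0, 1]")
            k_extra = 0
        V = V_of(lam_hat)
        beta, quad, loglik = _gls_profile(y, Z, V)
        _, quad_null, _ = _gls_profile(y, np.ones((n, 1)), V)
        self.lambda_ = lam_hat
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.loglik_ = loglik
        self.r2_ = 1.0 - quad / quad_null if quad_null > 0 else 1.0
        self.k_params_ = X.shape[1] + 2 + k_extra
        self.aic_, self.aicc_ = _aic_aicc(loglik, self.k_params_, n)
        self.n_obs_ = n
        self.species_ = labels
        L = cholesky(V, lower=True)
        Zs = solve_triangular(L, Z, lower=True)
        self.se_, self.pvalues_ = _wald_pvalues(Zs, quad, beta)
        return self

    def predict(self, X):
        X = _check_design(X, np.asarray(X).shape[0])
        return self.intercept_ + X @ self.coef_


def fit_pgls(y, X, tree: Phylogeny, lam="ML", species=None) -> PGLS:
    """Functional wrapper over :class:`PGLS`."""
    return PGLS(tree=tree, lam=lam).fit(X, y, species=species)


# ---------------------------------------------------------- phylogenetic signal
@dataclass
class SignalResult:
    """Phylogenetic signal of one trait: Blomberg's K with a permutation
    p-value and Pagel's λ with a likelihood-ratio p-value against λ=0."""

    K: float | None = None
    p_K: float | None = None
    lam: float | None = None
    p_lambda: float | None = None


def blomberg_k(
    trait, tree: Phylogeny, n_perm: int = 999, seed=None, species=None
) -> SignalResult:
    """Blomberg's K and its tip-permutation significance test.

    K is the ratio of the observed phylogenetically-corrected mean
    squared error ratio to its Brownian-motion expectation (≈ 1 under
    BM).  The p-value is the proportion of tip permutations (observed
    included) whose variance ratio is at least the observed one.
    """
    y = np.asarray(trait, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if np.unique(y).size < 2:
        raise DegenerateInputError("trait is constant across tips")
    labels = _match_labels(
        tree, species if species is not None else tree.tip_labels
    )
    if len(labels) != n:
        raise LabelsMismatchError(f"{len(labels)} labels for {n} observations")
    C = _phylo_cov(tree, labels)
    Cinv = np.linalg.inv(C + 1e-12 * np.trace(C) / n * np.eye(n))
    one = np.ones(n)
    w = Cinv @ one / (one @ Cinv @ one)

    def variance_ratio(vals: np.ndarray) -> np.ndarray:
        # vals: (m, n) rows of trait vectors
        a = vals @ w
        r = vals - a[:, None]
        num = (r * r).sum(axis=1)
        den = np.einsum("ij,jk,ik->i", r, Cinv, r)
        return num / den

    obs_ratio = float(variance_ratio(y[None, :])[0])
    expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    K = obs_ratio / expected
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    ratios = variance_ratio(perms)
    p = (1 + int((ratios >= obs_ratio - 1e-12).sum())) / (n_perm + 1)
    return SignalResult(K=float(K), p_K=float(p))


def pagel_lambda_signal(trait, tree: Phylogeny, species=None) -> SignalResult:
    """Intercept-only ML Pagel's λ on [0, 1] with an LR test against λ=0.

    Because λ=0 sits on the boundary of the parameter space, the LR
    statistic follows the 50:50 mixture of a point mass at zero and
    χ²(1) under the null, so the p-value is ½·P(χ²₁ ≥ LR) for LR > 0
    and 1 when the ML estimate coincides with the null.
    """
    y = np.asarray(trait, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("Pagel's lambda needs at least 4 tips")
    if np.unique(y).size < 2:
        raise DegenerateInputError("trait is constant across tips")
    empty = np.empty((n, 0))
    fit_ml = PGLS(tree=tree, lam="ML").fit(empty, y, species=species)
    fit_0 = PGLS(tree=tree, lam=0.0).fit(empty, y, species=species)
    lr = 2.0 * (fit_ml.loglik_ - fit_0.loglik_)
    if lr <= 1e-10:
        p = 1.0
    else:
        p = float(0.5 * chi2.sf(lr, df=1))
    return SignalResult(lam=fit_ml.lambda_, p_lambda=p)


def phylogenetic_signal(
    trait, tree: Phylogeny, n_perm: int = 999, seed=None, species=None
) -> SignalResult:
    """Blomberg's K and Pagel's λ for one trait."""
    rk = blomberg_k(trait, tree, n_perm=n_perm, seed=seed, species=species)
    rl = pagel_lambda_signal(trait, tree, species=species)
    return SignalResult(K=rk.K, p_K=rk.p_K, lam=rl.lam, p_lambda=rl.p_lambda)


# ------------------------------------------------------------ spatial weights
@dataclass
class SpatialWeights:
    """Neighbourhood weights over site centroids.

    ``B`` is the symmetric binary neighbour matrix (distance in
    (0, threshold]); ``W`` carries the scheme-specific weights.  Sites
    with no neighbour keep an all-zero row and are listed in
    ``isolated``.
    """

    coords: np.ndarray
    threshold: float
    scheme: str
    B: sp.csr_matrix = field(repr=False)
    W: sp.csr_matrix = field(repr=False)
    isolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return self.coords.shape[0]


_SCHEMES = ("row_standardized", "globally_standardized", "variance_stabilizing")


def build_spatial_weights(
    coords, threshold_km: float = 50.0, scheme: str = "row_standardized"
) -> SpatialWeights:
    """Binary neighbours within ``threshold_km`` (0 < d <= threshold),
    weighted by one of three standard coding schemes:

    * ``row_standardized``      w_ij = b_ij / Σ_j b_ij
    * ``globally_standardized`` w_ij = b_ij · n / Σ_ij b_ij
    * ``variance_stabilizing``  w_ij = b_ij / sqrt(Σ_j b_ij²), rescaled
      so the total weight equals n.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 sites with 2-D coordinates")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold_km, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d > 1e-12]  # strictly positive distance
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.array([], int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.array([], int)
    B = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray(B.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        logger.warning("%d sites have no neighbour within %.1f km",
                       isolated.size, threshold_km)
    with np.errstate(divide="ignore"):
        if scheme == "row_standardized":
            inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
            W = sp.diags(inv) @ B
        elif scheme == "globally_standardized":
            total = B.sum()
            W = B * (n / total) if total > 0 else B.copy()
        else:  # variance_stabilizing: q_i = sqrt(sum_j b_ij^2) = sqrt(deg_i)
            q = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1)), 0.0)
            Wstar = sp.diags(q) @ B
            total = Wstar.sum()
            W = Wstar * (n / total) if total > 0 else Wstar
    return SpatialWeights(coords, threshold_km, scheme, B.tocsr(), W.tocsr(),
                          isolated)


# ------------------------------------------------------------------ SAR error
class SARError(RegressorMixin, BaseEstimator):
    """Simultaneous autoregressive error model y = Xβ + u, u = ρWu + ε.

    ρ is estimated by maximum likelihood over the admissible interval
    given by the reciprocal extreme eigenvalues of W; the
    log-determinant term uses those eigenvalues directly.  With all
    weights zero the model reduces exactly to OLS.  ``r2_`` is the
    Nagelkerke pseudo-R² against the intercept-only non-spatial model.
    """

    model_tag = "SAR"

    def __init__(self, weights=None):
        self.weights = weights

    def fit(self, X, y):
        if self.weights is None:
            raise ValueError("SARError requires a SpatialWeights instance")
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        X = _check_design(X, n)
        p = X.shape[1]
        if n <= p + 2:
            raise ValueError(f"need n > p + 2 (n={n}, p={p})")
        if self.weights.n != n:
            raise ValueError("weights built on a different site set")
        Z = np.column_stack([np.ones(n), X])
        _rank_check(Z)
        W = self.weights.W
        null_ll = _gaussian_loglik(float(((y - y.mean()) ** 2).sum()), n)

        if W.nnz == 0:
            ols = OLS().fit(X, y)
            self.rho_ = 0.0
            self.coef_ = ols.coef_
            self.intercept_ = ols.intercept_
            self.loglik_ = ols.loglik_
            self.k_params_ = p + 3
            self.aic_, self.aicc_ = _aic_aicc(self.loglik_, self.k_params_, n)
            self.r2_ = float(np.clip(
                1.0 - np.exp(-(2.0 / n) * (self.loglik_ - null_ll)), 0.0, 1.0))
            self.n_obs_ = n
            self.se_, self.pvalues_ = ols.se_, ols.pvalues_
            return self

        eigs = np.linalg.eigvals(W.toarray())
        if np.abs(eigs.imag).max() > 1e-8:
            logger.warning("weight matrix has complex eigenvalues; using real parts")
        eigs = eigs.real
        emax = eigs.max()
        emin = eigs.min()
        margin = 1e-6
        hi = 1.0 / emax - margin if emax > 1e-12 else 1.0 - margin
        lo = 1.0 / emin + margin if emin < -1e-12 else -abs(hi)
        Wy = W @ y
        WZ = W @ Z

        def negll(rho):
            ys = y - rho * Wy
            Zs = Z - rho * WZ
            beta, _, _, _ = np.linalg.lstsq(Zs, ys, rcond=None)
            rss = float(((ys - Zs @ beta) ** 2).sum())
            logdet = float(np.log(np.maximum(1.0 - rho * eigs, 1e-300)).sum())
            return -(_gaussian_loglik(rss, n) + logdet)

        res = minimize_scalar(
            negll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        rho = float(res.x)
        if not np.isfinite(res.fun):
            raise ConvergenceError("SAR likelihood not finite at optimum")
        ys = y - rho * Wy
        Zs = Z - rho * WZ
        beta, _, _, _ = np.linalg.lstsq(Zs, ys, rcond=None)
        self.rho_ = rho
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.loglik_ = -float(res.fun)
        self.k_params_ = p + 3  # slopes + intercept + sigma^2 + rho
        self.aic_, self.aicc_ = _aic_aicc(self.loglik_, self.k_params_, n)
        self.r2_ = float(np.clip(
            1.0 - np.exp(-(2.0 / n) * (self.loglik_ - null_ll)), 0.0, 1.0))
        self.n_obs_ = n
        rss = float(((ys - Zs @ beta) ** 2).sum())
        self.se_, self.pvalues_ = _wald_pvalues(Zs, rss, beta)
        return self

    def predict(self, X):
        X = _check_design(X, np.asarray(X).shape[0])
        return self.intercept_ + X @ self.coef_


def fit_sar_error(y, X, weights: SpatialWeights) -> SARError:
    """Functional wrapper over :class:`SARError`."""
    return SARError(weights=weights).fit(X, y)


# -------------------------------------------------------- multimodel inference
@dataclass
class ModelSet:
    """All-subsets candidate models with AICc weights and averaged slopes.

    ``table`` holds one row per candidate (terms, aicc, delta, weight,
    confidence-set membership, per-term coefficients); ``averaged`` is
    the full (zero-substitution) model-averaged coefficient per
    predictor over the 95% confidence set, with weights renormalized
    inside the set.
    """

    predictors: list[str]
    table: pd.DataFrame
    averaged: pd.Series
    confidence_level: float = 0.95


MAX_SUBSET_PREDICTORS = 12


def multimodel_inference(
    y,
    X: pd.DataFrame,
    fitter=None,
    confidence_level: float = 0.95,
) -> ModelSet:
    """Fit every predictor subset (intercept-only included), weight by
    AICc, and average coefficients over the minimal weight-sorted prefix
    of models reaching ``confidence_level`` cumulative weight.

    ``fitter`` is a callable ``(X_subset, y) -> fitted estimator`` with
    ``aicc_``, ``coef_`` attributes; default OLS.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with named predictor columns")
    names = list(X.columns)
    p = len(names)
    if p < 1:
        raise ValueError("need at least one predictor")
    if p > MAX_SUBSET_PREDICTORS:
        raise CombinatorialLimitError(
            f"{p} predictors would enumerate {2**p} models "
            f"(limit {MAX_SUBSET_PREDICTORS})"
        )
    if fitter is None:
        fitter = lambda Xs, ys: OLS().fit(Xs, ys)
    y = np.asarray(y, dtype=float).ravel()
    rows = []
    for r in range(0, p + 1):
        for terms in itertools.combinations(names, r):
            Xs = X[list(terms)].to_numpy(dtype=float)
            fitted = fitter(Xs, y)
            rec = {
                "terms": terms,
                "n_terms": r,
                "aicc": fitted.aicc_,
                "loglik": getattr(fitted, "loglik_", np.nan),
            }
            for t, b in zip(terms, np.atleast_1d(fitted.coef_)):
                rec[f"coef_{t}"] = b
            rows.append(rec)
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    w = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    table["weight"] = w / w.sum()
    order = np.lexsort((np.arange(len(table)), -table["weight"].to_numpy()))
    cumw = np.cumsum(table["weight"].to_numpy()[order])
    m = int(np.searchsorted(cumw, confidence_level - 1e-12) + 1)
    conf_idx = order[:m]
    in_set = np.zeros(len(table), dtype=bool)
    in_set[conf_idx] = True
    table["in_confidence_set"] = in_set
    wt = table.loc[in_set, "weight"].to_numpy()
    wt = wt / wt.sum()
    averaged = {}
    sub = table[in_set]
    for name in names:
        col = f"coef_{name}"
        vals = sub[col].to_numpy(dtype=float) if col in sub else np.zeros(len(sub))
        vals = np.nan_to_num(vals, nan=0.0)  # zero-substitution averaging
        averaged[name] = float((wt * vals).sum())
    return ModelSet(
        predictors=names,
        table=table,
        averaged=pd.Series(averaged, name="averaged_coef"),
        confidence_level=confidence_level,
    )


def select_spatial_model(candidates: dict[str, object]) -> str:
    """Pick among fitted candidates (e.g. OLS + three SAR weight schemes)
    by lowest AIC, breaking near-ties (<1e-9) by highest R² and then by
    lower AIC again."""
    if not candidates:
        raise ValueError("no candidate models")
    items = list(candidates.items())
    items.sort(key=lambda kv: (round(kv[1].aic_, 9), -kv[1].r2_, kv[1].aic_))
    return items[0][0]
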