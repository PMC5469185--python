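"""Genetic risk score construction with internal elastic-net weights.

The unweighted GRS is the plain allele count summed over SNPs.  The
weighted GRS uses per-SNP weights taken from a multivariate penalized
logistic regression of the outcome on all SNPs jointly (the combined
marginal genetic effects), with the elastic-net penalty

    P(lambda, beta) = lambda * sum_j ( alpha |beta_j|
                                       + (1 - alpha)/2 beta_j^2 )

mixing lasso (alpha = 1) and ridge (alpha -> 0) components.  lambda is
chosen on a geometric path from lambda_max by K-fold cross-validated
binomial deviance, as in standard coordinate-descent elastic-net
software; coefficients are fit on standardized columns and reported
back on the original dosage scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit, xlogy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from ._cd import enet_logistic_path

__all__ = [
    "ALPHA_GRID_DEFAULT",
    "PenaltyConfig",
    "WeightVector",
    "ScoreVector",
    "GeneticRiskScorer",
    "fit_internal_weights",
    "grs_unweighted",
    "grs_weighted",
    "penalized_objective",
]

# Conventional grid of penalty weights (EN001 ... EN1).
ALPHA_GRID_DEFAULT = (0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class PenaltyConfig:
    """Elastic-net penalty configuration.

    alpha mixes the absolute (selection-inducing) and squared
    (grouping-inducing) penalty components; lambda_rule picks the
    overall strength on a cross-validated path ("cv-min" or "cv-1se")
    or fixes it ("fixed" with lambda_value).
    """

    alpha: float = 0.5
    lambda_rule: str = "cv-min"
    lambda_value: float | None = None
    n_folds: int = 10
    standardize: bool = True
    n_lambda: int = 40
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_rule not in ("cv-min", "cv-1se", "fixed"):
            raise ValueError(f"unknown lambda rule {self.lambda_rule!r}")
        if self.lambda_rule == "fixed":
            if self.lambda_value is None or self.lambda_value < 0:
                raise ValueError("fixed rule requires lambda_value >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class WeightVector:
    """Fitted per-SNP weights on the original genotype scale."""

    weights: np.ndarray
    intercept: float
    alpha: float
    lambda_selected: float
    converged: bool
    snp_names: list[str] | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def degenerate(self) -> bool:
        return self.n_nonzero == 0


@dataclass
class ScoreVector:
    """Per-subject genetic risk scores."""

    values: np.ndarray
    flavor: str  # "unweighted" | "weighted"
    degenerate: bool = False


def _as_dosage_matrix(genotypes, check_domain: bool = False) -> np.ndarray:
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional")
    if not np.all(np.isfinite(G)):
        raise ValueError("genotype matrix contains missing or non-finite values")
    if check_domain and not np.isin(G, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype dosages must be coded 0/1/2")
    return G


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(-2.0 * (xlogy(y, p) + xlogy(1 - y, 1 - p)).sum())


def _lambda_path(Z: np.ndarray, y: np.ndarray, cfg: PenaltyConfig) -> np.ndarray:
    n = len(y)
    # Smallest lambda with an all-zero solution (score equation at the
    # null model); alpha floored as in coordinate-descent software so a
    # near-ridge path stays finite.
    lmax = np.abs(Z.T @ (y - y.mean())).max() / (n * max(cfg.alpha, 1e-3))
    lmax = max(lmax, 1e-12)
    return np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambda)


def _path_fit(
    Z: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    outer_tol: float = 1e-9,
):
    """Warm-started coordinate-descent solutions along a lambda path.

    Yields (coef, intercept, converged) per lambda; the objective per
    observation is mean-NLL + lambda * P (see :mod:`grsxe._cd`).
    """
    yield from enet_logistic_path(Z, y, lams, alpha, tol=tol, outer_tol=outer_tol)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(len(y), dtype=int)
    idx = np.arange(len(y))
    for cls in np.unique(y):
        ii = idx[y == cls].copy()
        rng.shuffle(ii)
        folds[ii] = np.arange(len(ii)) % n_folds
    return folds


def fit_internal_weights(
    genotypes,
    outcome,
    penalty: PenaltyConfig | None = None,
    rng: np.random.Generator | None = None,
    snp_names: list[str] | None = None,
) -> WeightVector:
    """Elastic-net logistic weights for all SNPs jointly.

    The intercept is unpenalized.  Zero-variance columns are retained
    with weight 0 so the weight vector keeps the column dimension of
    the input.  With ``lambda_rule="fixed"`` and lambda_value = 0 an
    unpenalized maximum-likelihood fit is returned.
    """
    cfg = penalty or PenaltyConfig()
    rng = rng or np.random.default_rng()
    G = _as_dosage_matrix(genotypes)
    y = np.asarray(outcome, dtype=float).ravel()
    if G.shape[0] != len(y):
        raise ValueError("genotypes and outcome disagree on sample size")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; weights are not estimable")
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")

    n, p = G.shape
    sd = G.std(axis=0)
    keep = sd > 0
    if cfg.standardize:
        Z = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    else:
        Z = G[:, keep]

    def back_transform(coef: np.ndarray, icpt: float) -> tuple[np.ndarray, float]:
        w = np.zeros(p)
        if cfg.standardize:
            w[keep] = coef / sd[keep]
            icpt = icpt - float((coef * G[:, keep].mean(axis=0) / sd[keep]).sum())
        else:
            w[keep] = coef
        return w, icpt

    if not keep.any():
        # No informative columns at all: null model.
        return WeightVector(
            weights=np.zeros(p),
            intercept=float(logit(y.mean())),
            alpha=cfg.alpha,
            lambda_selected=np.inf,
            converged=True,
            snp_names=snp_names,
        )

    if cfg.lambda_rule == "fixed" and cfg.lambda_value == 0.0:
        clf = LogisticRegression(C=np.inf, solver="newton-cg", tol=1e-10, max_iter=500)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(Z, y)
            ok = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        w, icpt = back_transform(clf.coef_[0], float(clf.intercept_[0]))
        return WeightVector(w, icpt, cfg.alpha, 0.0, ok, snp_names)

    lams = _lambda_path(Z, y, cfg)

    if cfg.lambda_rule == "fixed":
        lam = float(cfg.lambda_value)
        if cfg.alpha > 0 and lam >= lams[0]:
            # KKT: beyond lambda_max the solution is exactly the null model
            return WeightVector(
                weights=np.zeros(p),
                intercept=float(logit(y.mean())),
                alpha=cfg.alpha,
                lambda_selected=lam,
                converged=True,
                snp_names=snp_names,
            )
        path = np.concatenate([lams[lams > lam], [lam]])
        for coef, icpt, ok in _path_fit(Z, y, path, cfg.alpha):
            pass
        w, icpt = back_transform(coef, icpt)
        return WeightVector(w, icpt, cfg.alpha, lam, ok, snp_names)

    # Cross-validated deviance along the path.
    folds = _stratified_folds(y.astype(int), cfg.n_folds, rng)
    dev = np.zeros((cfg.n_folds, len(lams)))
    for f in range(cfg.n_folds):
        tr = folds != f
        te = ~tr
        for k, (coef, icpt, _ok) in enumerate(
            _path_fit(Z[tr], y[tr], lams, cfg.alpha, tol=1e-7, outer_tol=1e-5)
        ):
            pr = expit(icpt + Z[te] @ coef)
            dev[f, k] = _binomial_deviance(y[te], pr) / te.sum()
    mean_dev = dev.mean(axis=0)
    if cfg.lambda_rule == "cv-min":
        k_sel = int(mean_dev.argmin())
    else:  # cv-1se
        k_min = int(mean_dev.argmin())
        se = dev[:, k_min].std(ddof=1) / np.sqrt(cfg.n_folds)
        ok_lams = np.flatnonzero(mean_dev <= mean_dev[k_min] + se)
        k_sel = int(ok_lams[0])  # path descends: first index = largest lambda

    for coef, icpt, ok in _path_fit(Z, y, lams[: k_sel + 1], cfg.alpha):
        pass
    w, icpt = back_transform(coef, icpt)
    return WeightVector(w, icpt, cfg.alpha, float(lams[k_sel]), ok, snp_names)


def grs_unweighted(genotypes) -> ScoreVector:
    """Plain risk-allele count: row sums of the 0/1/2 dosage matrix."""
    G = _as_dosage_matrix(genotypes, check_domain=True)
    return ScoreVector(values=G.sum(axis=1), flavor="unweighted")


def grs_weighted(genotypes, weights: WeightVector | np.ndarray) -> ScoreVector:
    """Weighted sum of risk-allele dosages (intercept excluded)."""
    G = _as_dosage_matrix(genotypes)
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if G.shape[1] != len(w):
        raise ValueError(
            f"weight vector has length {len(w)} but genotypes have "
            f"{G.shape[1]} columns"
        )
    degenerate = not np.any(w != 0)
    return ScoreVector(values=G @ w, flavor="weighted", degenerate=degenerate)


def penalized_objective(
    beta0: float,
    weights: np.ndarray,
    genotypes,
    outcome,
    lam: float,
    alpha: float,
) -> float:
    """Negative binomial log-likelihood plus elastic-net penalty.

    Returns  NLL(beta0, w) + n * lam * sum_j(alpha |w_j| +
    (1-alpha)/2 w_j^2); the intercept is unpenalized.  The n-scaling
    makes the minimizer match a fit whose per-observation objective is
    mean-NLL + lam * P, so lam here is on the same scale as
    ``WeightVector.lambda_selected``.  At lam = 0 this is exactly the
    negative log-likelihood.
    """
    G = _as_dosage_matrix(genotypes)
    y = np.asarray(outcome, dtype=float).ravel()
    w = np.asarray(weights, dtype=float)
    if G.shape[1] != len(w):
        raise ValueError("weights and genotype columns disagree")
    eta = beta0 + G @ w
    # log(1 + exp(eta)) - y*eta, computed stably
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    pen = float(len(y) * lam * np.sum(alpha * np.abs(w) + 0.5 * (1 - alpha) * w**2))
    return nll + pen


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a SNP dosage matrix to a genetic risk score.

    With ``weighting="elastic-net"`` (the default), :meth:`fit`
    estimates internal per-SNP weights by penalized multivariate
    logistic regression of the outcome on all SNP columns; with
    ``weighting="unweighted"`` the score is the plain allele count and
    ``fit`` only records the column dimension.

    Parameters
    ----------
    weighting : {"elastic-net", "unweighted"}
    alpha : float
        Elastic-net mixing weight in [0, 1]; 1 = lasso.
    lambda_rule : {"cv-min", "cv-1se", "fixed"}
        How the penalty strength is chosen.
    lambda_value : float, optional
        Penalty strength when ``lambda_rule="fixed"``.
    n_folds : int
        Cross-validation folds (outcome-stratified).
    standardize : bool
        Standardize columns internally; weights are always reported on
        the original dosage scale.
    random_state : int, optional
        Seeds the fold assignment.

    Attributes
    ----------
    weights_ : ndarray of shape (n_snps,)
    intercept_ : float
    lambda_selected_ : float
    n_nonzero_ : int
    converged_ : bool
    degenerate_ : bool
        True when every weight is zero (score carries no information).
    """

    def __init__(
        self,
        weighting: str = "elastic-net",
        alpha: float = 0.5,
        lambda_rule: str = "cv-min",
        lambda_value: float | None = None,
        n_folds: int = 10,
        standardize: bool = True,
        n_lambda: int = 40,
        lambda_min_ratio: float = 1e-3,
        random_state: int | None = None,
    ):
        self.weighting = weighting
        self.alpha = alpha
        self.lambda_rule = lambda_rule
        self.lambda_value = lambda_value
        self.n_folds = n_folds
        self.standardize = standardize
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.random_state = random_state

    def _penalty_config(self) -> PenaltyConfig:
        return PenaltyConfig(
            alpha=self.alpha,
            lambda_rule=self.lambda_rule,
            lambda_value=self.lambda_value,
            n_folds=self.n_folds,
            standardize=self.standardize,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )

    def fit(self, X, y=None):
        if self.weighting not in ("elastic-net", "unweighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        X = _as_dosage_matrix(X)
        self.n_features_in_ = X.shape[1]
        if self.weighting == "unweighted":
            self.weights_ = np.ones(X.shape[1])
            self.intercept_ = 0.0
            self.lambda_selected_ = np.nan
            self.converged_ = True
        else:
            if y is None:
                raise ValueError("elastic-net weighting requires an outcome y")
            wv = fit_internal_weights(
                X,
                y,
                penalty=self._penalty_config(),
                rng=np.random.default_rng(self.random_state),
            )
            self.weights_ = wv.weights
            self.intercept_ = wv.intercept
            self.lambda_selected_ = wv.lambda_selected
            self.converged_ = wv.converged
        self.n_nonzero_ = int(np.count_nonzero(self.weights_))
        self.degenerate_ = self.n_nonzero_ == 0
        return self

    def transform(self, X) -> np.ndarray:
        return self.score_vector(X).values[:, None]

    def score_vector(self, X) -> ScoreVector:
        """Scores as a :class:`ScoreVector` (1-d values plus flags)."""
        if not hasattr(self, "weights_"):
            raise AttributeError("scorer is not fitted")
        X = _as_dosage_matrix(X, check_domain=self.weighting == "unweighted")
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count changed between fit and transform")
        if self.weighting == "unweighted":
            return grs_unweighted(X)
        return grs_weighted(X, self.weights_)

    def weight_vector(self) -> WeightVector:
        if not hasattr(self, "weights_"):
            raise AttributeError("scorer is not fitted")
        return WeightVector(
            weights=self.weights_.copy(),
            intercept=self.intercept_,
            alpha=self.alpha if self.weighting == "elastic-net" else np.nan,
            lambda_selected=self.lambda_selected_,
            converged=self.converged_,
        )
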