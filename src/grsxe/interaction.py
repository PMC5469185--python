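"""Gene-environment interaction testing.

The primary analysis is a logistic regression of the binary outcome on
a genetic risk score, the exposure, their product, and optional
confounders,

    logit P(Y=1) = phi0 + phi1 GRS + phi2 E + phi3 GRS*E + sum_i d_i C_i

with a two-sided Wald test of the interaction coefficient phi3.  The
comparator is the common single-SNP scan (one such model per SNP with
the SNP in place of the GRS) with Bonferroni correction over all
scanned SNPs.  A median-dichotomized presentation with per-stratum
exposure odds ratios is provided for interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .scoring import ScoreVector

__all__ = [
    "InteractionFit",
    "SnpScanResult",
    "StratifiedEffect",
    "fit_gxe",
    "single_snp_scan",
    "summarize_best_snp",
    "dichotomize_and_stratify",
]


@dataclass
class InteractionFit:
    """Fitted GRS-by-exposure logistic interaction model."""

    phi0: float
    phi1: float
    phi2: float
    phi3: float
    delta: np.ndarray
    se: np.ndarray  # intercept, GRS, E, GRS*E, confounders
    p_interaction: float
    converged: bool
    degenerate: bool = False

    @property
    def or_interaction(self) -> float:
        return float(np.exp(self.phi3))


@dataclass
class SnpScanResult:
    """Single-SNP interaction scan with Bonferroni adjustment."""

    snp_names: list[str]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    n_tests: int

    @property
    def best_snp(self) -> str:
        return self.snp_names[int(np.argmin(self.p_adjusted))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.snp_names, "p_raw": self.p_raw, "p_adjusted": self.p_adjusted}
        )


@dataclass
class StratifiedEffect:
    """Exposure odds ratios within low/high GRS strata."""

    cut_value: float
    increment: float
    or_low: float | None
    ci_low: tuple[float, float] | None
    or_high: float | None
    ci_high: tuple[float, float] | None
    p_interaction: float
    n_low: int = 0
    n_high: int = 0
    undefined_reason: dict = field(default_factory=dict)


def _score_values(score) -> np.ndarray:
    if isinstance(score, ScoreVector):
        return np.asarray(score.values, dtype=float)
    return np.asarray(score, dtype=float).ravel()


def _null_fit(n_delta: int) -> InteractionFit:
    return InteractionFit(
        phi0=np.nan,
        phi1=np.nan,
        phi2=np.nan,
        phi3=np.nan,
        delta=np.full(n_delta, np.nan),
        se=np.full(4 + n_delta, np.nan),
        p_interaction=1.0,
        converged=False,
        degenerate=True,
    )


def fit_gxe(
    score,
    exposure,
    outcome,
    confounders=None,
    test: str = "wald",
) -> InteractionFit:
    """Fit the GRS-by-exposure interaction model.

    A degenerate (constant) score, perfect separation, or
    non-convergence yields a flagged fit with p_interaction = 1,
    counted downstream as a non-detection.  ``test`` selects the Wald
    (default) or likelihood-ratio p-value for the interaction term.
    """
    s = _score_values(score)
    e = np.asarray(exposure, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if not (len(s) == len(e) == len(y)):
        raise ValueError("score, exposure and outcome disagree on sample size")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
        raise ValueError("score and exposure must be finite")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; the model is not estimable")
    if test not in ("wald", "lr"):
        raise ValueError(f"unknown test {test!r}")

    C = None
    n_delta = 0
    if confounders is not None:
        C = np.atleast_2d(np.asarray(confounders, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        n_delta = C.shape[1]

    degenerate = np.ptp(s) == 0 or np.ptp(e) == 0
    if isinstance(score, ScoreVector) and score.degenerate:
        degenerate = True
    if degenerate:
        return _null_fit(n_delta)

    cols = [s, e, s * e]
    if C is not None:
        cols.extend(C.T)
    X = sm.add_constant(np.column_stack(cols))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            return _null_fit(n_delta)
        params = res.params
        bse = res.bse
        if not np.all(np.isfinite(bse)):
            return _null_fit(n_delta)
        p_int = float(res.pvalues[3])
        if test == "lr":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res0 = sm.Logit(y, np.delete(X, 3, axis=1)).fit(disp=0, maxiter=200)
            p_int = float(chi2.sf(2 * (res.llf - res0.llf), 1))
    except Exception:
        return _null_fit(n_delta)

    return InteractionFit(
        phi0=float(params[0]),
        phi1=float(params[1]),
        phi2=float(params[2]),
        phi3=float(params[3]),
        delta=np.asarray(params[4:], dtype=float),
        se=np.asarray(bse, dtype=float),
        p_interaction=p_int,
        converged=True,
    )


def single_snp_scan(
    genotypes,
    exposure,
    outcome,
    confounders=None,
    snp_names: list[str] | None = None,
) -> SnpScanResult:
    """One SNP-by-exposure interaction model per SNP, Bonferroni over all.

    Per-SNP failures (separation, non-convergence, monomorphic SNPs)
    are recorded as p = 1 and the scan continues.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional")
    p = G.shape[1]
    names = list(snp_names) if snp_names is not None else [f"snp{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("snp_names length must match genotype columns")
    p_raw = np.ones(p)
    for j in range(p):
        fit = fit_gxe(G[:, j], exposure, outcome, confounders=confounders)
        p_raw[j] = fit.p_interaction
    p_adj = np.minimum(1.0, p_raw * p)
    return SnpScanResult(snp_names=names, p_raw=p_raw, p_adjusted=p_adj, n_tests=p)


def summarize_best_snp(
    scan: SnpScanResult, risk_snp_ids, level: float = 0.05
) -> dict:
    """Per-risk-SNP rejection indicators from a Bonferroni-adjusted scan.

    Power for the single-SNP approach is summarized per risk SNP across
    replications and then maximized over the risk SNPs; this returns
    one replication's indicators plus their maximum (the family-wise
    "any risk SNP significant" indicator).
    """
    index = {name: i for i, name in enumerate(scan.snp_names)}
    indicators = {}
    for rid in risk_snp_ids:
        if rid not in index:
            raise KeyError(f"{rid!r} was not scanned")
        indicators[rid] = bool(scan.p_adjusted[index[rid]] < level)
    return {"indicators": indicators, "any": max(indicators.values(), default=False)}


def _exposure_or(e, y, confounders, increment):
    """Exposure odds ratio per ``increment`` with Wald 95% CI."""
    if len(np.unique(y)) < 2:
        return None, None, "single-class outcome in stratum"
    cols = [np.asarray(e, float)]
    if confounders is not None:
        C = np.atleast_2d(np.asarray(confounders, float))
        if C.shape[0] != len(y):
            C = C.T
        cols.extend(C.T)
    X = sm.add_constant(np.column_stack(cols))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False) or not np.isfinite(res.bse[1]):
            return None, None, "non-convergent stratum fit"
    except Exception:
        return None, None, "stratum fit failed"
    b, se = res.params[1], res.bse[1]
    or_pt = float(np.exp(b * increment))
    ci = (
        float(np.exp((b - 1.959964 * se) * increment)),
        float(np.exp((b + 1.959964 * se) * increment)),
    )
    return or_pt, ci, None


def dichotomize_and_stratify(
    score,
    exposure,
    outcome,
    confounders=None,
    increment: float = 1.0,
) -> StratifiedEffect:
    """Median-split GRS presentation of an interaction finding.

    The score is dichotomized at its median (ties to the low stratum)
    and the exposure odds ratio per ``increment`` units is reported
    within each stratum; the interaction p-value comes from the
    continuous-score model.
    """
    s = _score_values(score)
    if np.ptp(s) == 0:
        raise ValueError("score is constant; cannot dichotomize")
    e = np.asarray(exposure, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    cut = float(np.median(s))
    low = s <= cut
    high = ~low

    def sub(C, mask):
        if C is None:
            return None
        C2 = np.atleast_2d(np.asarray(C, float))
        if C2.shape[0] != len(y):
            C2 = C2.T
        return C2[mask]

    or_low, ci_low, why_low = _exposure_or(e[low], y[low], sub(confounders, low), increment)
    or_high, ci_high, why_high = _exposure_or(e[high], y[high], sub(confounders, high), increment)
    cont = fit_gxe(s, e, y, confounders=confounders)
    reasons = {}
    if why_low:
        reasons["low"] = why_low
    if why_high:
        reasons["high"] = why_high
    return StratifiedEffect(
        cut_value=cut,
        increment=increment,
        or_low=or_low,
        ci_low=ci_low,
        or_high=or_high,
        ci_high=ci_high,
        p_interaction=cont.p_interaction,
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        undefined_reason=reasons,
    )
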