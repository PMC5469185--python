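"""Synthetic cohort generation.

Builds case-control populations with the structure used throughout the
power study: six risk SNPs with fixed MAFs and odds ratios, optional
blocks of LD-correlated copies (a copy of a risk SNP with m entries
randomized, giving expected r^2 of (1 - m/N)^2), optional noise SNPs
generated independently of the outcome, a continuous exposure E, and a
binary outcome from a logistic model carrying same-direction
gene-environment interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._rng import substream
from .designs import (
    RISK_MAF,
    EffectDesign,
    EnvironmentSpec,
    ScenarioConfig,
)

__all__ = [
    "Population",
    "draw_genotypes",
    "make_correlated_copy",
    "make_noise_snp",
    "draw_environment",
    "calibrate_intercept",
    "simulate_outcome",
    "build_population",
    "nullify_environment",
]


@dataclass
class Population:
    """A generated cohort: genotype matrix, exposure, outcome, truth."""

    genotypes: np.ndarray  # (n, p) int8, entries 0/1/2
    exposure: np.ndarray  # (n,)
    outcome: np.ndarray  # (n,) 0/1
    snp_names: list[str]
    roles: list[str]  # per SNP: "risk" | "correlated" | "noise"
    source_map: dict[str, tuple[str, int]]  # correlated SNP -> (source, m)
    truth: EffectDesign
    config: ScenarioConfig | None = None
    intercept: float = field(default=np.nan)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def risk_snp_names(self) -> list[str]:
        return [s for s, r in zip(self.snp_names, self.roles) if r == "risk"]


def draw_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Additive genotype dosages: sum of two allele draws at ``maf``.

    Equivalent to Binomial(2, maf), i.e. Hardy-Weinberg proportions
    ((1-maf)^2, 2 maf (1-maf), maf^2) for dosages 0/1/2.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf must lie in [0, 1], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.binomial(2, maf, size=n).astype(np.int8)


def make_correlated_copy(
    source: np.ndarray, m: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy of ``source`` with exactly ``m`` entries freshly redrawn.

    The m positions are chosen uniformly without replacement and
    replaced by independent draws at the same MAF, so the expected
    squared correlation with the source is approximately (1 - m/N)^2.
    """
    source = np.asarray(source)
    n = source.shape[0]
    if not 0 <= m <= n:
        raise ValueError(f"m must lie in [0, {n}], got {m}")
    copy = source.copy()
    if m > 0:
        pos = rng.choice(n, size=m, replace=False)
        copy[pos] = draw_genotypes(maf, m, rng)
    return copy


def make_noise_snp(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """A SNP with no effect on the outcome: an independent fresh draw.

    Generated after the outcome, from its own random stream, so it
    cannot carry signal.
    """
    return draw_genotypes(maf, n, rng)


def draw_environment(
    n: int, distribution: EnvironmentSpec, rng: np.random.Generator
) -> np.ndarray:
    """Continuous exposure vector of length ``n``."""
    if distribution.name == "standard-normal":
        return rng.normal(0.0, 1.0, size=n)
    if distribution.name == "normal":
        mu, sd = distribution.params
        if sd == 0:
            warnings.warn(
                "degenerate exposure (sd = 0): constant vector; "
                "interaction tests downstream will be undefined",
                stacklevel=2,
            )
            return np.full(n, mu)
        return rng.normal(mu, sd, size=n)
    if distribution.name == "uniform":
        a, b = distribution.params
        return rng.uniform(a, b, size=n)
    raise ValueError(f"unknown environment distribution {distribution.name!r}")


def calibrate_intercept(linear_predictor: np.ndarray, target_prevalence: float) -> float:
    """Intercept c with mean(expit(c + lp)) == target_prevalence.

    Monotone in c, solved by bracketed root search to 1e-8.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite entries")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie strictly in (0, 1)")
    if np.ptp(lp) == 0:
        return float(logit(target_prevalence) - lp[0])

    def gap(c: float) -> float:
        return float(expit(c + lp).mean() - target_prevalence)

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_outcome(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    design: EffectDesign,
    rng: np.random.Generator,
    center_interaction: bool = True,
    return_intercept: bool = False,
):
    """Bernoulli outcome from the logistic gene-environment model.

    The linear predictor is

        c + sum_j b_g[j] G_j + b_e E + (sum_j b_gxe[j] Gc_j) E

    where Gc_j is the dosage centered at its expectation 2*maf_j when
    ``center_interaction`` is set (the default), and the raw dosage
    otherwise.  Centering leaves every single-SNP marginal interaction
    odds ratio unchanged while keeping the exposure main effect at
    b_e; see docs/methods.md.  The intercept c is calibrated so the
    expected prevalence equals ``design.target_prevalence``.
    """
    G = np.asarray(genotypes, dtype=float)
    E = np.asarray(exposure, dtype=float)
    if G.shape[0] != E.shape[0]:
        raise ValueError("genotypes and exposure disagree on sample size")
    if G.shape[1] != design.n_snps:
        raise ValueError(
            f"design has {design.n_snps} SNPs but genotypes have {G.shape[1]} columns"
        )
    Gi = G - 2.0 * design.maf[None, :] if center_interaction else G
    lp = G @ design.beta_g + design.beta_e * E + (Gi @ design.beta_gxe) * E
    c = calibrate_intercept(lp, design.target_prevalence)
    y = rng.binomial(1, expit(c + lp)).astype(np.int8)
    if return_intercept:
        return y, c
    return y


def build_population(config: ScenarioConfig) -> Population:
    """Assemble a full scenario population.

    Risk SNPs, exposure and outcome are generated first from the
    design; correlated copies and noise SNPs are added afterwards (the
    outcome depends on the risk SNPs and E only).  Every stage draws
    from its own named substream of ``config.seed``.
    """
    design = config.design()
    n = config.n_individuals
    seed = config.seed

    rng_g = substream(seed, "risk-genotypes")
    G_risk = np.column_stack(
        [draw_genotypes(m, n, rng_g) for m in design.maf]
    )
    E = draw_environment(n, config.environment, substream(seed, "environment"))
    y, intercept = simulate_outcome(
        G_risk,
        E,
        design,
        substream(seed, "outcome"),
        center_interaction=config.center_interaction,
        return_intercept=True,
    )

    columns = [G_risk]
    names = list(design.snp_names)
    roles = ["risk"] * design.n_snps
    source_map: dict[str, tuple[str, int]] = {}

    if config.n_correlated_per_risk_snp > 0:
        rng_c = substream(seed, "correlated")
        counts = config.randomization_counts[: config.n_correlated_per_risk_snp]
        corr_cols = []
        for j, src_name in enumerate(design.snp_names):
            for m in counts:
                col = make_correlated_copy(G_risk[:, j], m, design.maf[j], rng_c)
                corr_cols.append(col)
                name = f"{src_name}_{m}"
                names.append(name)
                roles.append("correlated")
                source_map[name] = (src_name, int(m))
        columns.append(np.column_stack(corr_cols))

    if config.n_noise > 0:
        rng_n = substream(seed, "noise")
        noise_mafs = np.resize(RISK_MAF, config.n_noise)
        noise_src = np.resize(np.arange(6), config.n_noise)
        noise_cols = []
        counters = dict.fromkeys(range(6), 0)
        for i in range(config.n_noise):
            noise_cols.append(make_noise_snp(noise_mafs[i], n, rng_n))
            j = int(noise_src[i])
            counters[j] += 1
            names.append(f"{design.snp_names[j]}_rand{counters[j]}")
            roles.append("noise")
        columns.append(np.column_stack(noise_cols))

    G = np.column_stack(columns).astype(np.int8)
    return Population(
        genotypes=G,
        exposure=E,
        outcome=y,
        snp_names=names,
        roles=roles,
        source_map=source_map,
        truth=design,
        config=config,
        intercept=intercept,
    )


def nullify_environment(pop: Population, rng: np.random.Generator) -> Population:
    """Null population: exposure replaced by a uniform random permutation.

    Genotypes and outcome are untouched, so any apparent interaction in
    the result is a false positive.
    """
    perm = rng.permutation(pop.n_individuals)
    return replace(pop, exposure=pop.exposure[perm])
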