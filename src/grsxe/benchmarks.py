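"""Headline operating characteristics of the GRS-by-E methods.

Reproduces the study-level quantities of the power comparison: power
of the weighted / unweighted GRS and the single-SNP Bonferroni scan in
the standard scenarios, the type-I error under the randomized-exposure
null, the marginal odds-ratio recovery of the generator, and the
discriminative accuracy (AUC) of the unweighted score.

Because every quantity is a Monte-Carlo estimate conditional on one
generated population, each benchmark averages over a small number of
independently regenerated populations (default 4) to remove the
population-realization noise that a single draw would impose; see
docs/methods.md for the problem sizes.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .cohort import Population, build_population
from .designs import ScenarioConfig
from .power import MethodSpec, estimate_power, estimate_type1
from .scoring import PenaltyConfig, WeightVector, fit_internal_weights

__all__ = [
    "power_benchmark",
    "type1_grid_benchmark",
    "auc_benchmark",
    "marginal_or_benchmark",
    "cohort_weights",
]

_POWER_REPS = 200
_N_POPULATIONS = 8


def _population(seed: int, tag: str, k: int, **scenario) -> Population:
    pop_seed = int(substream(seed, "population", tag, str(k)).integers(2**31))
    return build_population(ScenarioConfig(seed=pop_seed, **scenario))


def cohort_weights(pop: Population, alpha: float, rng) -> WeightVector:
    return fit_internal_weights(
        pop.genotypes,
        pop.outcome,
        penalty=PenaltyConfig(alpha=alpha),
        rng=rng,
        snp_names=list(pop.snp_names),
    )


def power_benchmark(
    seed: int,
    method: MethodSpec,
    n: int,
    design_label: str = "1.04",
    n_correlated_per_risk_snp: int = 0,
    n_noise: int = 0,
    reps: int = _POWER_REPS,
    n_populations: int = _N_POPULATIONS,
    mode: str = "power",
) -> float:
    """Rejection percentage, averaged over regenerated populations.

    For the single-SNP method the per-population summary is the
    maximum per-risk-SNP power after Bonferroni adjustment over all
    scanned SNPs.
    """
    tag = f"{mode}|{design_label}|c{n_correlated_per_risk_snp}|x{n_noise}|n{n}|{method.label}"
    estimate = estimate_power if mode == "power" else estimate_type1
    vals = []
    for k in range(n_populations):
        pop = _population(
            seed, tag, k,
            design_label=design_label,
            n_correlated_per_risk_snp=n_correlated_per_risk_snp,
            n_noise=n_noise,
        )
        weights = None
        if method.kind == "weighted-grs":
            weights = cohort_weights(pop, method.alpha, substream(seed, "weights", tag, str(k)))
        est = estimate(pop, n, reps, method, substream(seed, "mc", tag, str(k)), weights=weights)
        vals.append(est.proportion)
    return float(np.mean(vals) * 100.0)


def type1_grid_benchmark(
    seed: int,
    reps: int = 1500,
    sample_sizes: tuple[int, ...] = (400, 700, 1000),
) -> dict:
    """Type-I error of the GRS methods across the <=68-SNP scenarios.

    Returns the per-cell proportions (percent), their maximum over all
    (scenario, n, method) cells, and the single-SNP family-wise error
    in the 68-SNP scenario.
    """
    scenarios = {
        "design1": {},
        "corr42": {"n_correlated_per_risk_snp": 7},
        "noise20": {"n_noise": 20},
    }
    uw = MethodSpec("unweighted-grs")
    en = MethodSpec("weighted-grs", alpha=0.5)
    cells = {}
    for name, extra in scenarios.items():
        pop = _population(seed, f"type1|{name}", 0, design_label="1.04", **extra)
        w = cohort_weights(pop, 0.5, substream(seed, "type1-weights", name))
        for n in sample_sizes:
            for method, weights in ((uw, None), (en, w)):
                est = estimate_type1(
                    pop, n, reps, method,
                    substream(seed, "type1-mc", name, str(n), method.label),
                    weights=weights,
                )
                cells[f"{name}|n{n}|{method.label}"] = est.proportion * 100.0

    pop68 = _population(
        seed, "type1|68snp", 0, design_label="1.04",
        n_correlated_per_risk_snp=7, n_noise=20,
    )
    scan = estimate_type1(
        pop68, 700, max(200, reps // 3), MethodSpec("single-snp-bonferroni"),
        substream(seed, "type1-mc", "68snp"),
    )
    return {
        "cells": cells,
        "max_grs": max(cells.values()),
        "single_snp_familywise": scan.familywise * 100.0,
        "reps": reps,
    }


def auc_benchmark(seed: int, n_populations: int = _N_POPULATIONS) -> float:
    """AUC of the six-SNP unweighted allele count for the outcome."""
    from sklearn.metrics import roc_auc_score

    aucs = []
    for k in range(n_populations):
        pop = _population(seed, "auc", k, design_label="1.04")
        score = pop.genotypes[:, :6].astype(float).sum(axis=1)
        aucs.append(roc_auc_score(pop.outcome, score))
    return float(np.mean(aucs))


def marginal_or_benchmark(seed: int, n_populations: int = _N_POPULATIONS) -> dict:
    """Single-SNP marginal OR(G) estimates at N = 10,000.

    Averaged over regenerated populations (on the log-odds scale) so
    the check reflects the generator, not one sampling draw.
    """
    import statsmodels.api as sm

    logs: dict[str, list[float]] = {}
    for k in range(n_populations):
        pop = _population(seed, "marginal", k, design_label="1.04")
        G = pop.genotypes.astype(float)
        for j, name in enumerate(pop.snp_names[:6]):
            X = sm.add_constant(np.column_stack([G[:, j], pop.exposure]))
            res = sm.Logit(pop.outcome, X).fit(disp=0)
            logs.setdefault(name, []).append(float(res.params[1]))
    return {name: float(np.exp(np.mean(v))) for name, v in logs.items()}
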