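"""Monte-Carlo power and type-I-error estimation.

Small analysis cohorts of size n are resampled with replacement from a
fixed generated population of N = 10,000, the chosen analysis (GRS
interaction test or single-SNP Bonferroni scan) is applied to each,
and power is the fraction of replications rejecting at p < 0.05.  The
type-I error uses the same machinery with the exposure freshly
permuted within each resampled cohort, destroying any true
interaction while preserving the marginal structure.

By default the internal elastic-net weights of the weighted GRS are
estimated once on the full cohort and reused across replications;
``refit_weights=True`` re-estimates them inside every replication
instead (see docs/methods.md for the trade-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .cohort import Population, build_population
from .designs import ScenarioConfig
from .interaction import fit_gxe, single_snp_scan
from .scoring import PenaltyConfig, WeightVector, fit_internal_weights, grs_weighted

__all__ = [
    "MethodSpec",
    "PowerEstimate",
    "resample",
    "estimate_power",
    "estimate_type1",
    "run_scenario_grid",
]

_KINDS = ("unweighted-grs", "weighted-grs", "single-snp-bonferroni")


@dataclass(frozen=True)
class MethodSpec:
    """An analysis method entering the power comparison."""

    kind: str
    alpha: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown method kind {self.kind!r}")
        if (self.kind == "weighted-grs") != (self.alpha is not None):
            raise ValueError("alpha must be given exactly for weighted-grs methods")
        if not self.label:
            default = {
                "unweighted-grs": "UW",
                "single-snp-bonferroni": "bestSNP",
            }.get(self.kind) or "EN" + f"{self.alpha:g}".replace("0.", "0").replace(
                ".", ""
            )
            object.__setattr__(self, "label", default)


@dataclass
class PowerEstimate:
    """Rejection proportion across replications with its MC uncertainty."""

    proportion: float
    n_replications: int
    mode: str  # "power" | "type1"
    method: MethodSpec
    sample_size: int
    scenario: ScenarioConfig | None = None
    per_snp: dict = field(default_factory=dict)
    familywise: float | None = None

    @property
    def mc_se(self) -> float:
        p = self.proportion
        return float(np.sqrt(p * (1 - p) / self.n_replications))


def resample(pop: Population, n: int, rng: np.random.Generator) -> Population:
    """Sub-cohort of n rows drawn uniformly with replacement."""
    if pop.n_individuals == 0:
        raise ValueError("population is empty")
    if n < 1:
        raise ValueError("resample size must be >= 1")
    idx = rng.integers(0, pop.n_individuals, size=n)
    return replace(
        pop,
        genotypes=pop.genotypes[idx],
        exposure=pop.exposure[idx],
        outcome=pop.outcome[idx],
    )


def _cohort_weights(pop: Population, method: MethodSpec, rng) -> WeightVector:
    return fit_internal_weights(
        pop.genotypes,
        pop.outcome,
        penalty=PenaltyConfig(alpha=method.alpha),
        rng=rng,
        snp_names=list(pop.snp_names),
    )


def _grs_pvalue(g, e, y, method, weights, rng, refit):
    if method.kind == "unweighted-grs":
        score = g.astype(float).sum(axis=1)
    else:
        if refit:
            try:
                weights = fit_internal_weights(
                    g, y, penalty=PenaltyConfig(alpha=method.alpha), rng=rng
                )
            except ValueError:
                return 1.0
        sv = grs_weighted(g, weights)
        if sv.degenerate:
            return 1.0
        score = sv.values
    try:
        return fit_gxe(score, e, y).p_interaction
    except ValueError:
        return 1.0  # e.g. single-class resample: counted as non-detection


def _run(
    pop: Population,
    n: int,
    reps: int,
    method: MethodSpec,
    rng: np.random.Generator,
    mode: str,
    level: float,
    refit_weights: bool,
    weights: WeightVector | None = None,
) -> PowerEstimate:
    if reps < 1:
        raise ValueError("need at least one replication")
    if method.kind == "weighted-grs" and not refit_weights and weights is None:
        weights = _cohort_weights(pop, method, rng)

    risk_ids = pop.risk_snp_names()
    risk_idx = [pop.snp_names.index(r) for r in risk_ids]
    rej_snp = np.zeros(len(risk_ids))
    rej_any = 0
    rej = 0
    for _ in range(reps):
        idx = rng.integers(0, pop.n_individuals, size=n)
        g = pop.genotypes[idx].astype(float)
        e = pop.exposure[idx]
        y = pop.outcome[idx]
        if mode == "type1":
            e = rng.permutation(e)
        if method.kind == "single-snp-bonferroni":
            scan = single_snp_scan(g, e, y, snp_names=list(pop.snp_names))
            hits = scan.p_adjusted[risk_idx] < level
            rej_snp += hits
            rej_any += bool(hits.any())
        else:
            rej += _grs_pvalue(g, e, y, method, weights, rng, refit_weights) < level

    if method.kind == "single-snp-bonferroni":
        per_snp = {r: rej_snp[i] / reps for i, r in enumerate(risk_ids)}
        proportion = max(per_snp.values())
        fam = rej_any / reps
    else:
        per_snp = {}
        proportion = rej / reps
        fam = None
    return PowerEstimate(
        proportion=float(proportion),
        n_replications=reps,
        mode=mode,
        method=method,
        sample_size=n,
        scenario=pop.config,
        per_snp=per_snp,
        familywise=fam,
    )


def estimate_power(
    population: Population,
    n: int,
    reps: int,
    method: MethodSpec,
    rng: np.random.Generator,
    level: float = 0.05,
    refit_weights: bool = False,
    weights: WeightVector | None = None,
) -> PowerEstimate:
    """Rejection proportion under the generated (true-interaction) model.

    For the single-SNP method the proportion reported is the maximum
    per-risk-SNP power; the family-wise summary ("any risk SNP
    significant" per replication) is returned alongside.  A
    pre-computed cohort-level ``weights`` vector may be supplied to
    avoid re-fitting it on every call.
    """
    return _run(population, n, reps, method, rng, "power", level, refit_weights, weights)


def estimate_type1(
    population: Population,
    n: int,
    reps: int,
    method: MethodSpec,
    rng: np.random.Generator,
    level: float = 0.05,
    refit_weights: bool = False,
    weights: WeightVector | None = None,
) -> PowerEstimate:
    """Rejection proportion with E permuted within each resampled cohort."""
    return _run(population, n, reps, method, rng, "type1", level, refit_weights, weights)


def run_scenario_grid(
    grid: Iterable[tuple[ScenarioConfig, int, MethodSpec, int]],
    master_seed: int = 0,
    modes: Sequence[str] = ("power", "type1"),
    level: float = 0.05,
    refit_weights: bool = False,
) -> pd.DataFrame:
    """Evaluate every (scenario, n, method, reps) cell in both modes.

    Populations are generated once per distinct scenario and shared
    across cells.  Each cell draws from a substream derived from the
    master seed and the cell's content, so results are independent of
    grid order.
    """
    pops: dict[ScenarioConfig, Population] = {}
    rows = []
    for config, n, method, reps in grid:
        if config not in pops:
            pops[config] = build_population(config)
        pop = pops[config]
        for mode in modes:
            key = f"cell|{config.design_label}|{config.n_correlated_per_risk_snp}|" \
                  f"{config.n_noise}|{n}|{method.label}|{mode}|{reps}"
            rng = substream(master_seed, key)
            try:
                est = _run(pop, n, reps, method, rng, mode, level, refit_weights)
                rows.append(
                    {
                        "design": config.design_label,
                        "n_correlated": 6 * config.n_correlated_per_risk_snp,
                        "n_noise": config.n_noise,
                        "n": n,
                        "method": method.label,
                        "alpha": method.alpha,
                        "mode": mode,
                        "proportion": est.proportion,
                        "reps": reps,
                        "mc_se": est.mc_se,
                        "error": "",
                    }
                )
            except Exception as exc:  # record and continue
                rows.append(
                    {
                        "design": config.design_label,
                        "n_correlated": 6 * config.n_correlated_per_risk_snp,
                        "n_noise": config.n_noise,
                        "n": n,
                        "method": method.label,
                        "alpha": method.alpha,
                        "mode": mode,
                        "proportion": np.nan,
                        "reps": reps,
                        "mc_se": np.nan,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
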