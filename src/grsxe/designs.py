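"""Effect designs and simulation scenario configuration.

The base cohort emulates a simulated age-related macular degeneration
(AMD) case-control population of 10,000 subjects with six established
risk SNPs.  Three built-in gene-environment interaction designs share
the genetic main effects and minor-allele frequencies but differ in the
strength of the per-SNP interaction with a continuous exposure E,
labelled by the approximate mean interaction odds ratio across the six
SNPs (1.01, 1.04, 1.05).  All odds ratios are per risk allele (additive
coding) and, for E, per unit of exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EffectDesign",
    "ScenarioConfig",
    "EnvironmentSpec",
    "risk_design",
    "RISK_SNP_NAMES",
    "RISK_MAF",
    "RISK_OR_MARGINAL",
    "DESIGN_LABELS",
    "DEFAULT_EXPOSURE_SD",
    "DEFAULT_RANDOMIZATION_COUNTS",
]

RISK_SNP_NAMES: tuple[str, ...] = (
    "CFHrs1061170",
    "LOCrs10490924",
    "CFHrs1410996",
    "C2rs9332739",
    "CFBrs641153",
    "CFHrs2230199",
)

RISK_MAF = np.array([0.50, 0.33, 0.30, 0.07, 0.12, 0.27])

# Per-SNP marginal genetic main-effect odds ratios (single-SNP fits),
# identical across designs.  These are the reference values the
# generated cohorts reproduce.
RISK_OR_MARGINAL = np.array([1.32, 1.76, 1.32, 3.08, 1.13, 1.28])

# Conditional (joint-model) per-allele odds ratios used for outcome
# generation.  Single-SNP marginal fits are attenuated relative to the
# conditional effects by non-collapsibility of the odds ratio (the
# omitted other-SNP and interaction terms act as unexplained
# variance), so the conditional values were calibrated by a simulated
# fixed-point iteration at N = 400,000 such that marginal refits on a
# generated cohort recover RISK_OR_MARGINAL.  See docs/methods.md.
_OR_G = np.array([1.369, 1.860, 1.376, 3.466, 1.150, 1.317])

# Per-design exposure main effect and per-SNP interaction odds ratios.
_DESIGNS: dict[str, tuple[float, tuple[float, ...]]] = {
    "1.01": (1.03, (1.01, 1.01, 1.01, 1.01, 1.03, 1.01)),
    "1.04": (1.05, (1.02, 1.04, 1.02, 1.03, 1.06, 1.06)),
    "1.05": (1.12, (1.03, 1.05, 1.03, 1.06, 1.07, 1.07)),
}
DESIGN_LABELS = tuple(_DESIGNS)

# Exposure standard deviation, in exposure units.  The interaction and
# exposure odds ratios above are per unit; the unit scale was calibrated
# by censored maximum likelihood so that single-SNP interaction tests on
# the full cohort reproduce the per-SNP significance pattern of the
# reference designs.  See docs/methods.md.
DEFAULT_EXPOSURE_SD = 6.5

# Randomized-entry counts for the 7 LD copies per risk SNP; predicted
# r^2 = (1 - m/N)^2 at N = 10,000 spans {0.98 ... 0.30}.
DEFAULT_RANDOMIZATION_COUNTS: tuple[int, ...] = (100, 500, 1000, 1500, 2500, 3500, 4500)

_LABEL_TOL = 0.015  # design "1.01" actually averages 1.0133


@dataclass(frozen=True)
class EffectDesign:
    """Generative truth for a cohort: per-SNP effects plus globals.

    ``beta_g`` and ``beta_gxe`` are log odds ratios per risk allele;
    ``beta_e`` is the log odds ratio per unit of exposure.  The
    intercept is calibrated at generation time to hit
    ``target_prevalence`` and is not stored here.
    """

    snp_names: tuple[str, ...]
    maf: np.ndarray
    beta_g: np.ndarray
    beta_gxe: np.ndarray
    beta_e: float
    target_prevalence: float = 0.40
    design_label: str = "custom"

    def __post_init__(self) -> None:
        maf = np.asarray(self.maf, dtype=float)
        bg = np.asarray(self.beta_g, dtype=float)
        bgxe = np.asarray(self.beta_gxe, dtype=float)
        object.__setattr__(self, "maf", maf)
        object.__setattr__(self, "beta_g", bg)
        object.__setattr__(self, "beta_gxe", bgxe)
        k = len(self.snp_names)
        if not (len(maf) == len(bg) == len(bgxe) == k):
            raise ValueError("per-SNP fields must share one length")
        if np.any((maf <= 0) | (maf >= 1)):
            raise ValueError("risk-SNP MAFs must lie strictly in (0, 1)")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if self.design_label in _DESIGNS:
            mean_or = float(np.exp(bgxe).mean())
            if abs(mean_or - float(self.design_label)) > _LABEL_TOL:
                raise ValueError(
                    f"mean interaction OR {mean_or:.4f} inconsistent with "
                    f"design label {self.design_label}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)


def risk_design(label: str, target_prevalence: float = 0.40) -> EffectDesign:
    """Built-in six-SNP design for a given mean interaction OR label."""
    if label not in _DESIGNS:
        raise ValueError(f"unknown design {label!r}; expected one of {DESIGN_LABELS}")
    or_e, or_gxe = _DESIGNS[label]
    return EffectDesign(
        snp_names=RISK_SNP_NAMES,
        maf=RISK_MAF.copy(),
        beta_g=np.log(_OR_G),
        beta_gxe=np.log(np.asarray(or_gxe)),
        beta_e=float(np.log(or_e)),
        target_prevalence=target_prevalence,
        design_label=label,
    )


@dataclass(frozen=True)
class EnvironmentSpec:
    """Distribution of the continuous exposure E."""

    name: str = "normal"
    params: tuple[float, ...] = (0.0, DEFAULT_EXPOSURE_SD)

    def __post_init__(self) -> None:
        if self.name not in ("normal", "standard-normal", "uniform"):
            raise ValueError(f"unknown environment distribution {self.name!r}")
        if self.name == "uniform" and not self.params[0] < self.params[1]:
            raise ValueError("uniform bounds must satisfy a < b")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: design, LD copies, noise SNPs, exposure."""

    design_label: str = "1.04"
    n_individuals: int = 10_000
    n_correlated_per_risk_snp: int = 0
    n_noise: int = 0
    randomization_counts: tuple[int, ...] = DEFAULT_RANDOMIZATION_COUNTS
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    target_prevalence: float = 0.40
    center_interaction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_correlated_per_risk_snp < 0 or self.n_noise < 0:
            raise ValueError("SNP counts must be non-negative")
        if self.n_correlated_per_risk_snp > 0 and len(self.randomization_counts) < self.n_correlated_per_risk_snp:
            raise ValueError(
                "need one randomization count per correlated copy "
                f"({self.n_correlated_per_risk_snp} requested, "
                f"{len(self.randomization_counts)} provided)"
            )
        for m in self.randomization_counts[: self.n_correlated_per_risk_snp]:
            if not 0 <= m <= self.n_individuals:
                raise ValueError("randomization counts must lie in [0, n_individuals]")

    @property
    def n_snps_total(self) -> int:
        return 6 + 6 * self.n_correlated_per_risk_snp + self.n_noise

    def design(self) -> EffectDesign:
        return risk_design(self.design_label, self.target_prevalence)

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)
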