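"""Shared fixtures: generated populations and cohort-level weights.

The expensive N = 10,000 scenario populations and their cohort-level
elastic-net weights are session-scoped so the acceptance tests share
them.  All seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from grsxe import (
    MethodSpec,
    PenaltyConfig,
    ScenarioConfig,
    build_population,
    fit_internal_weights,
    substream,
)

# One fixed study seed for the full-size populations.
STUDY_SEED = 20170612


def _pop(**kw):
    return build_population(ScenarioConfig(seed=STUDY_SEED, **kw))


@pytest.fixture(scope="session")
def pop_d104():
    """Design 1.04, six risk SNPs only, N = 10,000."""
    return _pop(design_label="1.04")


@pytest.fixture(scope="session")
def pop_d104_noise20():
    return _pop(design_label="1.04", n_noise=20)


@pytest.fixture(scope="session")
def pop_d104_corr42():
    return _pop(design_label="1.04", n_correlated_per_risk_snp=7)


@pytest.fixture(scope="session")
def pop_d105():
    return _pop(design_label="1.05")


@pytest.fixture(scope="session")
def pop_d101():
    return _pop(design_label="1.01")


def _cohort_weights(pop):
    return fit_internal_weights(
        pop.genotypes,
        pop.outcome,
        penalty=PenaltyConfig(alpha=0.5),
        rng=substream(STUDY_SEED, "cohort-weights"),
        snp_names=list(pop.snp_names),
    )


@pytest.fixture(scope="session")
def weights_d104(pop_d104):
    return _cohort_weights(pop_d104)


@pytest.fixture(scope="session")
def weights_d104_noise20(pop_d104_noise20):
    return _cohort_weights(pop_d104_noise20)


@pytest.fixture(scope="session")
def weights_d104_corr42(pop_d104_corr42):
    return _cohort_weights(pop_d104_corr42)


@pytest.fixture(scope="session")
def weights_d105(pop_d105):
    return _cohort_weights(pop_d105)


@pytest.fixture(scope="session")
def weights_d101(pop_d101):
    return _cohort_weights(pop_d101)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


EN05 = MethodSpec("weighted-grs", alpha=0.5)
UW = MethodSpec("unweighted-grs")
BEST_SNP = MethodSpec("single-snp-bonferroni")
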