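"""Synthetic cohort generator: distributional and structural checks."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from grsxe import (
    EnvironmentSpec,
    ScenarioConfig,
    build_population,
    calibrate_intercept,
    draw_environment,
    draw_genotypes,
    make_correlated_copy,
    make_noise_snp,
    nullify_environment,
    risk_design,
    simulate_outcome,
    substream,
)
from grsxe.designs import RISK_MAF, RISK_SNP_NAMES, EffectDesign


class TestDrawGenotypes:
    def test_extreme_frequencies(self, rng):
        assert not draw_genotypes(0.0, 100, rng).any()
        assert (draw_genotypes(1.0, 100, rng) == 2).all()

    def test_out_of_range_maf_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_genotypes(-0.1, 10, rng)
        with pytest.raises(ValueError):
            draw_genotypes(1.2, 10, rng)

    def test_mean_dosage(self, rng):
        g = draw_genotypes(0.33, 10_000, rng)
        se = np.sqrt(2 * 0.33 * 0.67 / 10_000)
        assert abs(g.mean() - 0.66) < 3 * se

    @pytest.mark.parametrize("maf", [0.07, 0.27, 0.50])
    def test_hardy_weinberg_proportions(self, maf, rng):
        n = 10_000
        g = draw_genotypes(maf, n, rng)
        expected = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        for k in (0, 1, 2):
            se = np.sqrt(expected[k] * (1 - expected[k]) / n)
            assert abs((g == k).mean() - expected[k]) < 4 * se

    @given(maf=st.floats(0, 1), n=st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dosage_domain(self, maf, n):
        g = draw_genotypes(maf, n, np.random.default_rng(0))
        assert np.isin(g, (0, 1, 2)).all()


class TestCorrelatedCopy:
    def test_no_randomization_is_identity(self, rng):
        src = draw_genotypes(0.3, 500, rng)
        assert (make_correlated_copy(src, 0, 0.3, rng) == src).all()

    def test_full_randomization_is_independent(self, rng):
        n, reps = 400, 200
        src = draw_genotypes(0.3, n, rng)
        r2 = [
            np.corrcoef(src, make_correlated_copy(src, n, 0.3, rng))[0, 1] ** 2
            for _ in range(reps)
        ]
        # mean r^2 of independent vectors is ~ 1/(n-1)
        assert np.mean(r2) < 3.0 / (n - 1)

    def test_expected_r2_half(self, rng):
        n, m, reps = 10_000, 2929, 200
        src = draw_genotypes(0.33, n, rng)
        r2 = np.mean(
            [
                np.corrcoef(src, make_correlated_copy(src, m, 0.33, rng))[0, 1] ** 2
                for _ in range(reps)
            ]
        )
        assert abs(r2 - 0.50) < 0.03  # (1 - m/n)^2 = 0.4999

    def test_m_exceeding_length_rejected(self, rng):
        with pytest.raises(ValueError):
            make_correlated_copy(np.zeros(10, dtype=np.int8), 11, 0.3, rng)

    @given(m=st.integers(0, 60))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exactly_m_entries_can_change(self, m):
        rng = np.random.default_rng(7)
        src = draw_genotypes(0.5, 60, rng)
        copy = make_correlated_copy(src, m, 0.5, rng)
        assert (copy != src).sum() <= m


class TestNoiseSnps:
    def test_reproducible_under_fixed_seed(self):
        a = make_noise_snp(0.5, 4, substream(3, "noise"))
        b = make_noise_snp(0.5, 4, substream(3, "noise"))
        assert (a == b).all()

    def test_independent_streams_uncorrelated(self):
        n = 5000
        a = make_noise_snp(0.3, n, substream(3, "noise-a")).astype(float)
        b = make_noise_snp(0.3, n, substream(3, "noise-b")).astype(float)
        assert abs(np.corrcoef(a, b)[0, 1]) < 3 / np.sqrt(n)

    def test_noise_purity_null_rejection_rate(self, rng):
        """Interaction tests on a noise SNP reject at ~5% across regenerations."""
        design = risk_design("1.04")
        n, gens = 1500, 200
        rej = 0
        pvals = []
        for _ in range(gens):
            G = np.column_stack([draw_genotypes(m, n, rng) for m in design.maf])
            E = rng.normal(0, 6.5, n)
            y = simulate_outcome(G, E, design, rng)
            noise = make_noise_snp(0.3, n, rng).astype(float)
            X = sm.add_constant(np.column_stack([noise, E, noise * E]))
            p = sm.Logit(y, X).fit(disp=0).pvalues[3]
            pvals.append(p)
            rej += p < 0.05
        assert 0.03 <= rej / gens <= 0.07
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestEnvironment:
    def test_standard_normal_mean(self, rng):
        e = draw_environment(10_000, EnvironmentSpec("standard-normal", ()), rng)
        assert abs(e.mean()) < 3 / np.sqrt(10_000)

    def test_uniform_support(self, rng):
        e = draw_environment(5, EnvironmentSpec("uniform", (0.0, 1.0)), rng)
        assert ((e >= 0) & (e <= 1)).all()

    def test_degenerate_sd_warns(self, rng):
        with pytest.warns(UserWarning, match="degenerate"):
            e = draw_environment(10, EnvironmentSpec("normal", (2.0, 0.0)), rng)
        assert np.ptp(e) == 0

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentSpec("lognormal", (0.0, 1.0))


class TestCalibrateIntercept:
    def test_closed_forms(self):
        lp = np.zeros(100)
        assert calibrate_intercept(lp, 0.5) == pytest.approx(0.0, abs=1e-8)
        assert calibrate_intercept(lp, 0.25) == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)

    def test_root_find_hits_target(self, rng):
        from scipy.special import expit

        lp = rng.normal(size=2000)
        c = calibrate_intercept(lp, 0.4)
        assert abs(expit(c + lp).mean() - 0.4) < 1e-6

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept(np.array([0.0, np.inf]), 0.4)
        with pytest.raises(ValueError):
            calibrate_intercept(np.zeros(3), 1.0)


class TestSimulateOutcome:
    def test_null_design_prevalence(self, rng):
        design = EffectDesign(
            snp_names=("a", "b"),
            maf=np.array([0.3, 0.4]),
            beta_g=np.zeros(2),
            beta_gxe=np.zeros(2),
            beta_e=0.0,
            target_prevalence=0.5,
        )
        G = np.column_stack([draw_genotypes(m, 5000, rng) for m in design.maf])
        y = simulate_outcome(G, rng.normal(size=5000), design, rng)
        assert abs(y.mean() - 0.5) < 3 * np.sqrt(0.25 / 5000)

    def test_dimension_mismatch_rejected(self, rng):
        design = risk_design("1.04")
        with pytest.raises(ValueError):
            simulate_outcome(np.zeros((10, 3)), np.zeros(10), design, rng)

    def test_joint_model_recovers_interaction_truth(self, pop_d104):
        """A correctly specified joint refit recovers the generative
        interaction OR of the strongest-interaction SNP (1.06)."""
        G = pop_d104.genotypes[:, :6].astype(float)
        E = pop_d104.exposure
        design = pop_d104.truth
        Gc = G - 2 * design.maf[None, :]
        X = sm.add_constant(np.column_stack([G, E[:, None], Gc * E[:, None]]))
        res = sm.Logit(pop_d104.outcome, X).fit(disp=0, maxiter=200)
        j = list(RISK_SNP_NAMES).index("CFHrs2230199")
        est = float(np.exp(res.params[7 + j]))
        se = float(res.bse[7 + j])
        assert abs(np.log(est) - np.log(1.06)) < 3 * se

    def test_marginal_main_effects_match_design(self, pop_d104):
        """Single-SNP logistic ORs for G recover the reference marginal
        odds ratios within 10% for all six risk SNPs."""
        from grsxe.designs import RISK_OR_MARGINAL

        G = pop_d104.genotypes.astype(float)
        E = pop_d104.exposure
        y = pop_d104.outcome
        target = RISK_OR_MARGINAL
        for j in range(6):
            X = sm.add_constant(np.column_stack([G[:, j], E]))
            res = sm.Logit(y, X).fit(disp=0)
            # 10% band, widened to 3 SEs for rare SNPs whose single-draw
            # sampling error exceeds it
            tol = max(np.log(1.10), 3 * res.bse[1])
            assert abs(res.params[1] - np.log(target[j])) < tol

    def test_null_interaction_pvalues_uniform(self, rng):
        """With no interaction in truth and permuted E, the GRS-by-E
        Wald p-value is uniform across regenerated populations."""
        from grsxe import fit_gxe, grs_unweighted

        design = EffectDesign(
            snp_names=tuple(RISK_SNP_NAMES),
            maf=RISK_MAF.copy(),
            beta_g=risk_design("1.04").beta_g,
            beta_gxe=np.zeros(6),
            beta_e=np.log(1.05),
            target_prevalence=0.4,
        )
        pvals = []
        for _ in range(200):
            G = np.column_stack([draw_genotypes(m, 800, rng) for m in design.maf])
            E = rng.normal(0, 6.5, 800)
            y = simulate_outcome(G, E, design, rng)
            pvals.append(fit_gxe(grs_unweighted(G), rng.permutation(E), y).p_interaction)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBuildPopulation:
    def test_68_snp_scenario(self, pop_d104_noise20, pop_d104_corr42):
        config = ScenarioConfig(
            design_label="1.04", n_correlated_per_risk_snp=7, n_noise=20, seed=5
        )
        assert config.n_snps_total == 68
        pop = build_population(config)
        assert pop.genotypes.shape == (10_000, 68)
        assert pop.roles.count("risk") == 6
        assert pop.roles.count("correlated") == 42
        assert pop.roles.count("noise") == 20

    def test_minimal_scenario_has_six_columns(self):
        pop = build_population(ScenarioConfig(n_individuals=200, seed=1))
        assert pop.genotypes.shape == (200, 6)
        assert all(r == "risk" for r in pop.roles)

    def test_correlated_r2_spans_stated_range(self, pop_d104_corr42):
        pop = pop_d104_corr42
        for name, (src, m) in pop.source_map.items():
            j = pop.snp_names.index(name)
            k = pop.snp_names.index(src)
            r2 = np.corrcoef(pop.genotypes[:, j], pop.genotypes[:, k])[0, 1] ** 2
            assert 0.25 <= r2 <= 1.0
            assert abs(r2 - (1 - m / 10_000) ** 2) < 0.05

    def test_prevalence_near_target(self, pop_d104):
        se = np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(pop_d104.outcome.mean() - 0.4) < 3 * se

    def test_adding_noise_does_not_perturb_risk_block(self):
        a = build_population(ScenarioConfig(n_individuals=500, seed=9))
        b = build_population(ScenarioConfig(n_individuals=500, n_noise=20, seed=9))
        assert (a.genotypes == b.genotypes[:, :6]).all()
        assert (a.outcome == b.outcome).all()
        assert (a.exposure == b.exposure).all()

    def test_scenario_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_individuals=0)
        with pytest.raises(ValueError):
            ScenarioConfig(n_individuals=50, randomization_counts=(100,) * 7,
                           n_correlated_per_risk_snp=7)


class TestNullifyEnvironment:
    def test_is_a_permutation(self, rng):
        pop = build_population(ScenarioConfig(n_individuals=300, seed=2))
        null = nullify_environment(pop, rng)
        assert np.allclose(np.sort(null.exposure), np.sort(pop.exposure))
        assert (null.genotypes == pop.genotypes).all()
        assert (null.outcome == pop.outcome).all()
        again = nullify_environment(null, rng)
        assert np.allclose(np.sort(again.exposure), np.sort(pop.exposure))

    def test_breaks_exposure_outcome_link(self, rng):
        pop = build_population(ScenarioConfig(n_individuals=2000, seed=3))
        cors = [
            abs(np.corrcoef(nullify_environment(pop, rng).exposure, pop.outcome)[0, 1])
            for _ in range(50)
        ]
        assert np.mean(cors) < 3 / np.sqrt(2000)


def test_design_label_mean_interaction_or():
    for label in ("1.01", "1.04", "1.05"):
        d = risk_design(label)
        assert abs(np.exp(d.beta_gxe).mean() - float(label)) < 0.015
        assert (d.beta_gxe >= 0).all()  # same-direction interactions
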