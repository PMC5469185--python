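# grsxe — internally weighted genetic risk scores for GxE interaction testing

Single-SNP scans for gene–environment (GxE) interactions are
underpowered: realistic per-SNP interaction odds ratios (1.01–1.06)
vanish under Bonferroni correction.  When the interactions of a
pathway's SNPs point in the same direction, aggregating the SNPs into
a genetic risk score (GRS) and testing one score-by-exposure term
recovers that power.  The catch is the weights: published external
weights rarely exist for the outcome at hand.  `grsxe` implements the
internal-weights alternative — per-SNP weights estimated from the
study's own data by a multivariate **elastic-net logistic regression**
— together with the simulation machinery to quantify when it works.

For SNP dosages G_1..G_k (coded 0/1/2), outcome Y and exposure E:

- unweighted score: GRS_uw = Σ_j G_j
- weighted score: GRS_w = Σ_j β̂_j G_j, with β̂ from the penalized
  multivariate fit of Y on all SNPs jointly, elastic-net penalty
  λ Σ_j (α|β_j| + (1−α)/2 β_j²), λ chosen by 10-fold cross-validated
  deviance on a warm-started coordinate-descent path
- interaction model: logit P(Y=1) = φ₀ + φ₁·GRS + φ₂·E + φ₃·GRS×E
  (+ confounders), two-sided Wald test of φ₃
- comparator: per-SNP models Y ~ G_j + E + G_j×E with Bonferroni
  correction over all scanned SNPs

The package ships a synthetic-cohort generator (six AMD-style risk
SNPs with fixed MAFs and odds ratios, LD-correlated copies with r²
from 0.30 to 0.98, outcome-independent noise SNPs, a continuous
exposure) and a bootstrap engine estimating power and type-I error
from resampled sub-cohorts.  See `docs/methods.md` for the model, the
calibration of the generator, and its limitations.

## Worked example

```python
import numpy as np
from grsxe import (ScenarioConfig, build_population, GeneticRiskScorer,
                   fit_gxe, single_snp_scan)

config = ScenarioConfig(design_label="1.04", n_correlated_per_risk_snp=7,
                        n_noise=20, seed=7)
pop = build_population(config)
print(f"cohort: {pop.n_individuals} subjects, {pop.n_snps} SNPs "
      f"(6 risk + 42 correlated + 20 noise), prevalence {pop.outcome.mean():.3f}")

scorer = GeneticRiskScorer(alpha=0.5, random_state=1)   # sklearn-style
scorer.fit(pop.genotypes, pop.outcome)
print(f"elastic net (alpha=0.5): lambda={scorer.lambda_selected_:.4f}, "
      f"{scorer.n_nonzero_}/{pop.n_snps} SNPs kept")

fit = fit_gxe(scorer.score_vector(pop.genotypes), pop.exposure, pop.outcome)
print(f"weighted GRSxE: OR={fit.or_interaction:.3f} per score unit "
      f"per exposure unit, p={fit.p_interaction:.2e}")

scan = single_snp_scan(pop.genotypes, pop.exposure, pop.outcome,
                       snp_names=list(pop.snp_names))
j = int(np.argmin(scan.p_adjusted))
print(f"best single SNP: {scan.snp_names[j]}, Bonferroni p={scan.p_adjusted[j]:.2e}")
```

prints

```
cohort: 10000 subjects, 68 SNPs (6 risk + 42 correlated + 20 noise), prevalence 0.401
elastic net (alpha=0.5): lambda=0.0104, 28/68 SNPs kept
weighted GRSxE: OR=1.068 per score unit per exposure unit, p=1.23e-22
best single SNP: CFHrs2230199_100, Bonferroni p=2.55e-15
```

The elastic net keeps 28 of 68 SNPs — it prunes the noise block and
thins the LD block — and the score-level interaction test is many
orders of magnitude more significant than the best Bonferroni-adjusted
single SNP on the same cohort.

The same cohort supports a small-study power comparison (n = 700
resampled with replacement, 400 replications; weights estimated once
on the full cohort):

```python
from grsxe import MethodSpec, estimate_power, estimate_type1, substream
from grsxe.benchmarks import cohort_weights

pop = build_population(ScenarioConfig(design_label="1.04", n_noise=20, seed=7))
w = cohort_weights(pop, 0.5, substream(7, "weights"))
for method, weights in ((MethodSpec("weighted-grs", alpha=0.5), w),
                        (MethodSpec("unweighted-grs"), None),
                        (MethodSpec("single-snp-bonferroni"), None)):
    power = estimate_power(pop, 700, 400, method, substream(7, "pw", method.label),
                           weights=weights)
    null = estimate_type1(pop, 700, 400, method, substream(7, "t1", method.label),
                          weights=weights)
    print(f"{method.label:>8}: power {100*power.proportion:5.1f}%  "
          f"type-I error {100*null.proportion:4.1f}%")
```

```
    EN05: power  71.8%  type-I error  5.8%
      UW: power  36.0%  type-I error  4.2%
 bestSNP: power  22.2%  type-I error  0.2%
```

With 20 noise SNPs diluting the plain allele count, the weighted score
nearly doubles the power of the unweighted one at the same nominal
type-I error; the Bonferroni scan is both weakest and most
conservative.

## Command line

Every stage is also a `grsxe` subcommand (thin wrappers over the
library), each writing a replayable run manifest:

```sh
grsxe simulate --design 1.04 --correlated 7 --noise 20 --seed 1 -o pop/
grsxe weights pop/cohort.tsv --alpha 0.5 --seed 1 -o w/
grsxe test pop/cohort.tsv --method en05 --stratify
grsxe scan pop/cohort.tsv
grsxe power --design 1.04 --n 700 --reps 200 --method en05 --seed 1
grsxe type1 --design 1.04 --n 700 --reps 200 --method uw --seed 1
grsxe grid --config grid.yaml --seed 1 -o results.tsv
```

Cohorts are plain TSV (one row per subject; SNP dosage columns, then
`E` and `Y`) with a JSON sidecar holding roles, LD source map and the
generative truth; a PLINK `.raw`-style export is available.

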