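# snpepi

Two-locus SNP case-control association and epistasis analysis.

`snpepi` is a reusable, tested pipeline for the classic two-SNP
case-control design in genetic epidemiology: two biallelic variants
(the motivating application is TP53 R72P × MDM2 T309G in a
cervical-screening cohort of women stratified by HIV status), binary
outcomes, and a handful of categorical covariates. It is aimed at
biostatisticians and genetic epidemiologists who want the full analysis
sequence — descriptive tables, exact tests, model scans, confounder
selection, mediation checks, pattern-driven model discovery and power
analysis — as composable, scriptable pieces rather than a point-and-click
workflow.

## What it computes

**Encodings.** A genotype is coded 0 (homozygous wild), 1
(heterozygous), 2 (homozygous variant). Five standard single-SNP genetic
models (codominant, overdominant, additive, dominant, recessive) recode
one SNP into regression terms; a catalog of 13 two-locus epistatic
models recodes the 9 genotype combinations into a reference category
plus one or two effect categories (or a numeric score). The catalog
includes dominant/recessive epistasis in both locus orders, double
dominant/recessive forms with and without cumulative effects, the
allele-count quantitative model, and the *blocked-recessive* models: a
double dominant effect that also masks a recessive effect which
surfaces only in the wild-homozygote × variant-homozygote combinations.

**Exact tests.** Hardy-Weinberg equilibrium is tested exactly,
conditional on the observed allele counts; r×c contingency tables get a
two-sided Fisher exact test (full enumeration, with a seeded
Monte-Carlo fallback for large tables) or a Pearson chi-square.
Two-sided p-values follow probability-mass ordering.

**Association.** Odds ratios come from maximum-likelihood logistic
regression on complete cases, crude and covariate-adjusted, with Wald
95% CIs and one block likelihood-ratio p-value per model
(OR = e^β; for a categorical encoding the block test has as many
degrees of freedom as non-reference categories). Confounders are chosen
by stepwise-backward selection (likelihood-ratio tests, critical
P = 0.2, skin colour always retained) run against both the outcome and
the genetic exposure (multinomial logistic for multi-level exposures);
the analysis adjusts for the covariates retained on both sides.
Mediation is assessed by refitting with the putative mediator as an
extra covariate and reporting the attenuation of each OR.

**Discovery.** The 9-level combined genotype is profiled against the
outcome in one adjusted fit; an explicit, auditable rule (elevation over
the median OR of the other combinations, mutual similarity) decides
whether the blocked-recessive pattern is present and proposes the
corresponding models.

**Power.** Rejection rates of the block test are estimated by
simulation at a grid of odds ratios (default 1.25, 1.5, 2.0, 3.0 and
their protective reciprocals), with deterministic per-replicate random
substreams and scenarios below 0.80 power flagged as underpowered.

**Synthetic cohorts.** A generator draws cohorts with per-stratum
genotype frequencies, covariate distributions, MCAR missingness and
logistic outcome models; `mimic_params()` is a preset that emulates the
motivating study's marginal distributions (250 + 100 women), and
`inject_effect()` plants a known effect on any encoding with the
intercept re-solved to hold a target prevalence — the basis of the
parameter-recovery and calibration test suites.

## Worked example

The headline result of the motivating study is the blocked-recessive
pattern against HIV status. Its three-way partition counts (controls
50/180/20, cases 8/70/22 across reference / middle / blocked categories)
expand to a subject-level cohort and refit in a few lines:

```python
from snpepi import DesignSpec, epistatic_exposure, fit_logistic
from snpepi.simulate import discussion_cohort

cohort = discussion_cohort()   # 350 subjects from the printed counts
cat = fit_logistic(cohort, DesignSpec("hiv", epistatic_exposure("9.1")))
for c in cat.contrasts:
    print(f"{c.label}: OR {c.format_or()}")
lin = fit_logistic(cohort, DesignSpec("hiv", epistatic_exposure("9.2")))
print(f"per step: OR {lin.contrasts[0].format_or()}, block p = {lin.block_p:.2g}")
```

prints

```
R72P _309_ - _72_ T309G - P72P G309G: OR 2.43 (1.10-5.39)
R72R G309G - P72P T309T: OR 6.88 (2.63-17.98)
per step: OR 2.66 (1.65-4.28), block p = 2.8e-05
```

— carriers of a variant at either locus have about 2.4-fold odds of
being in the case group, the two "blocked" combinations about 6.9-fold,
and the linear score multiplies the odds by 2.66 per step. Descriptive
statistics reproduce the same way:

```python
from snpepi import fisher_exact, hwe_exact
from snpepi.simulate import pooled_genotype_counts, study_contingency_tables

hwe_exact(pooled_genotype_counts(2)).p_value           # 0.102  (T309G, HWE)
fisher_exact(study_contingency_tables()["g1"]).p_value # 0.200  (R72P x HIV)
```

## Command line

```sh
snpepi simulate --n-controls 250 --n-cases 100 --seed 9 --out cohort.csv
snpepi describe --input cohort.csv --out-dir out    # Table-1-style report + HWE
snpepi analyze  --input cohort.csv --out-dir out    # scans, mediation, OR profile
snpepi power    --family epistasis --replicates 1000 --out-dir out
snpepi fixtures --out-dir fixtures                  # worked-example tables
```

`analyze` writes one delimited file per report table (single-SNP scans
per locus and outcome, epistasis scans, mediation re-analysis, the
combined-genotype OR profile and the pattern-rule trace) plus a JSON run
log with the seed and every confounder-selection trace.

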