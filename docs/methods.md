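# Methods

This note records the statistical procedures `snpepi` implements, the
assumptions behind them, the defaults and why they were chosen, and the
known limitations. It is the package's own account; every number quoted
here is computed by the test suite or the acceptance script.

## Data model

A cohort is a per-subject table with two ordinal genotypes (0/1/2 =
homozygous wild / heterozygous / homozygous variant), three binary
outcomes (HIV status; HPV status; HPV oncogenic risk, defined only
among HPV-positive subjects) and four categorical covariates (skin
colour, age group, schooling, family income). Any value may be missing;
the nested outcome is hard-validated: a non-missing oncogenic-risk value
for a subject who is not HPV-positive is rejected, not silently fixed.
Genotype cells in files may be 0/1/2 codes or allele-pair labels
("R72P", "G309G", ...): both parse to the same internal ordinal coding,
so the pipeline is independent of locus naming.

The two strata of the motivating study are treated as independent
groups of 250 and 100 subjects, as its descriptive table is laid out.
(The source reports conflicting stratum labels in places — its abstract
and descriptive table disagree on which group has 250 members, and the
printed HPV percentages conflict with the surrounding text's direction.
The package reproduces the table's counts as printed and does not
adjudicate the labels; nothing downstream depends on which stratum is
called "positive".)

## Descriptive layer

Counts and percentages are computed per variable on complete cases
within each stratum — a variable with missing values uses its own
reduced denominator, matching how such tables are conventionally
printed. Between-strata comparisons default to the two-sided Fisher
exact test, with Pearson chi-square for variables configured that way
(age group and skin colour by default, following the motivating
analysis: the chi-square value is what its skin-colour p-value of 0.005
corresponds to; the Fisher exact value on the same counts is 0.0059).

**Exact HWE.** The Hardy-Weinberg test conditions on the observed
allele counts: given n subjects and the minor-allele count, the
heterozygote count has the exact null distribution
P(h) ∝ 2^h n! / (x! h! z!) over counts with the right parity, and the
p-value sums the probabilities of all configurations no more probable
than the observed one. Monomorphic samples return p = 1. The test is
run on the pooled ("total") sample and within skin-colour strata; the
pooling choice reproduces the published total-sample values (e.g.
p = 0.102 for the promoter SNP, counts 51/146/153).

**Fisher r×c.** Two-sided p by probability-mass ordering: the sum of
multivariate hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed the observed one,
with a relative slack of 1e-7 in the comparison (without it, ties at
the observed probability are broken by floating-point noise and the
published values are not reproduced). Enumeration is exact up to 4×4
tables with n ≤ 500 and at most 2 × 10⁶ enumerated tables; beyond
either cap the p-value is estimated from 10⁶ Patefield-sampled tables
with a fixed seed and an add-one correction, and the Monte-Carlo
standard error is reported. All tables of the motivating study fall in
the exact range.

## Encodings

Single-SNP genetic models map the three genotype classes to regression
terms: codominant (two indicators), additive (allele count, one numeric
column), overdominant, dominant and recessive (one indicator each). The
reference is always the category containing the wild homozygote.

The 13 epistatic models are total maps from the 9 two-locus genotype
combinations to a reference plus 1–2 categories or a score, validated
at import time against the partition invariant (disjoint categories
covering all 9 combinations). Three definitions in the catalog deserve
a note, because the printed sources are inconsistent:

* **Model 1.1** (dominant epistasis, locus 1 over locus 2): category 1
  is "wild-homozygous at locus 1 and variant carrier at locus 2"
  (`R72R G309_`), following the methods text; one of the printed result
  tables labels the same contrast `R72P G309_`, which would overlap
  category 2 and cannot partition.
* **Model 2.2** (recessive epistasis, locus 2 over locus 1): category 1
  is implemented as the locus-swapped mirror of model 2.1 — variant
  homozygote at locus 1 and not at locus 2 — since the printed label
  (`R72R T309_`) overlaps the reference. The mirror reading is the only
  partition consistent with the model being "vice-versa" of 2.1.
* **Model 9.1** (blocked recessive): the middle category is the
  complement of {wild/wild} ∪ {wild × variant-homozygote pair} — six
  combinations — which is the only reading consistent with the
  published three-way counts (50/180/20 and 8/70/22).

Ordinal models (additive, allele-count model 8, score model 9.2) enter
regression as a single numeric column; categorical models as
reference-coded indicators. Model 9.2's score is the category index of
model 9.1 (0/1/2), and model 8's score is the sum of the two additive
encodings — both identities are asserted by enumeration in the tests.
Custom categorical models can be registered through
`make_categorical_model`, which enforces the partition invariant.

## Association fits

All fits are maximum-likelihood binary logistic regressions
(Newton-Raphson, log-likelihood tolerance 1e-8, at most 100 iterations,
BFGS fallback) on complete cases: subjects missing the outcome, a
needed genotype or any covariate of that fit are dropped and excluded
from `n_used`. Choices that the published analysis leaves open, fixed
here for determinism:

* **Block p-value**: likelihood-ratio test of all exposure terms
  jointly (2 df for three-category models), comparing against the same
  covariate-only model on the same subjects. The motivating analysis
  prints one p per model and uses likelihood-ratio tests elsewhere, so
  the LRT is the natural reading; it is also invariant to the choice of
  reference category (tested).
* **Confidence intervals** are Wald intervals on the log-odds scale.
  Some published intervals are consistent with profile likelihood
  instead, so CIs are treated as descriptive output, not as quantities
  to reproduce; point estimates on collapsed tables are exact
  cross-product ratios and are reproduced to printed precision.
* **Covariate coding**: reference-coded indicators with the most
  frequent level as reference.
* **Separation** is flagged, not corrected: any exposure coefficient
  with |log OR| > 15 marks the contrast unstable and the fit
  non-converged. Penalised estimates are deliberately not substituted —
  sparse categories should surface as the extremely wide intervals they
  are. Empty exposure categories are reported as undefined contrasts
  and excluded from the design; the rest of the fit proceeds.
* **Significance convention**: p < 0.05 significant, 0.05 ≤ p < 0.10
  marginal.

**Confounder selection** is stepwise-backward with likelihood-ratio
drop-one tests at critical P = 0.2: at each step the removable
covariate with the largest p ≥ 0.2 is removed and the model refitted.
Skin colour is locked (never removed) as the population-stratification
control. Selection is run once per outcome (binary logistic) and once
per genetic exposure — genotype (3 levels) or combined genotype (9
levels, wild/wild reference) by multinomial logistic regression — and
an exposure-outcome analysis adjusts for the union of the locked set
with the covariates retained on both sides. Complete cases over the
target and all candidates are used throughout a selection so every step
compares the same subjects. Note the P = 0.2 criterion retains a truly
null covariate about 20% of the time by construction; the tests check
the retention *rate*, not any single run.

**Mediation** follows the covariate-inclusion design of the motivating
analysis: the adjusted model is refitted with the putative mediator
(HIV status) added, on the subjects complete for both fits, and the
attenuation 1 − log(OR_with)/log(OR_without) is reported per contrast
(≈0 irrelevant mediator, ≈1 full mediation). No indirect-effect
decomposition is attempted — with a binary outcome and logistic links,
simple covariate inclusion conflates mediation with non-collapsibility,
which is a stated limitation, not an oversight.

## Pattern discovery

The discovery step reproduces, as an explicit rule, what was originally
a visual inspection: profile the 9-level combined genotype against the
outcome in one adjusted fit (reference wild/wild), then flag
combinations whose OR exceeds an elevation multiple (default 2.0) of
the median OR of the remaining combinations, requiring flagged ORs to
be mutually similar (max/min ratio ≤ 1.5 by default). Only when the
flagged set is exactly the wild-homozygote × variant-homozygote pair
are the blocked-recessive models proposed. The thresholds are declared
defaults, not values inferred from data — the original judgment was
qualitative and there is nothing to estimate them from; every
comparison the rule makes is written to an audit trace, and the rule is
scale-equivariant (it only compares OR ratios).

## Synthetic cohorts

The generator draws, per stratum: the joint two-locus genotype from
independent per-locus frequencies (optionally tilted by a log-linear
dependence parameter, P(g1,g2) ∝ P(g1)P(g2)e^{ld·g1·g2}, or replaced by
an explicit joint table), covariates from categorical distributions,
outcomes from logistic models evaluated on the complete latent data,
and missingness last — so missingness is MCAR by construction and
complete-case analysis is unbiased in the recovery suites. Fixed seed
gives a bit-identical cohort; a receipt records the seed, a parameter
digest and realized counts.

`mimic_params()` encodes the motivating study's conditions: strata of
250 and 100; genotype frequencies (27,118,105)/250 and (35,101,114)/250
in one stratum, (18,43,39)/100 and (16,45,39)/100 in the other;
covariate distributions from the descriptive table; income and
schooling missingness matching its reduced denominators; HPV status and
oncogenic risk logistic in stratum membership at the printed
prevalences. Only marginals are published, so loci are independent
within stratum by default. The published three-way blocked-recessive
counts are internally inconsistent with those marginals (their
reference category is larger than the wild-homozygote count of the same
stratum); the mimic preset follows the marginal table and the worked
example follows the three-way counts verbatim — the two are deliberately
not forced to agree.

`inject_effect` plants a known effect on any encoding: coefficients are
log odds ratios on the model's own terms (both non-reference categories
receive the same log OR when a single value is supplied, matching how
power tables index effects by one OR per model) and the intercept is
re-solved by root bracketing to 1e-6 on the probability scale so the
marginal prevalence stays at its target (default 0.3).

## Power analysis

A power scenario fixes an encoding, an effect OR, group sizes (study
preset 250/100, pooled study genotype frequencies), alpha = 0.05 and a
target prevalence (default the case fraction). Each replicate draws
genotype counts multinomially, outcomes binomially from the logistic
model, and computes the matching block test. Because crude fits depend
on the data only through the exposure-level × outcome table, replicates
are evaluated on collapsed counts: the saturated categorical block LRT
equals the G statistic of the k×2 table, and ordinal scores are fitted
by Newton iterations on the aggregated binomial — the tests pin both
shortcuts to the subject-level fits. Per-replicate generators are
spawned from the root seed, so estimates are reproducible and
replicates exchangeable. The default grid is OR ∈ {1.25, 1.5, 2.0, 3.0}
plus reciprocals, 1000 replicates, with power < 0.80 flagged
underpowered. Default replicate counts and the simulation sizes used in
the test suite (e.g. recovery at n = 20 000, calibration at 2000
replicates) are the package's chosen trade-off between Monte-Carlo
error and runtime.

## What passing tests do and do not show

The synthetic generator reproduces marginal distributions, MCAR
missingness and logistic outcomes. It does not emulate linkage
disequilibrium beyond a single tilt parameter, covariate-genotype
dependence (population structure) unless configured, informative
missingness, genotyping error, or the joint covariate structure of the
real cohort. Parameter-recovery and calibration results therefore
validate the estimators under the stated model, not the robustness of
the original study's conclusions to violations of it. Published
*adjusted* ORs depend on unavailable individual-level data and are out
of reach by design; everything recomputable from printed counts (exact
test p-values, crude collapsed-table ORs) is reproduced to printed
precision.
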