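# Methods

This note documents the models, rules and numerical choices behind
`famseg`, and what its synthetic-data validation does and does not show.

## Study design being modelled

The reference cohort consists of 439 multiplex late-onset Alzheimer
disease (LOAD) families: each reports at least four demented relatives,
with family mean onset ≥ 60 y. One proband per family (the youngest
affected with the most definitive diagnosis) was sequenced for rare
(MAF < 5%) missense, nonsense and splice-site variants in *APP*,
*PSEN1*, *PSEN2*, *MAPT* and *GRN*; confirmed variants were then
genotyped in all available relatives and in external case, control and
unselected panels. The package takes those genotype/phenotype tables as
input; it does not touch raw sequencing data, and in-silico predictions
(missense damage calls, splice-site scores) are consumed as labels.

## Segregation rules

For one family and one variant, only genotyped members with known
affection enter the 2×2 partition; MCI ("questionable dementia")
individuals are excluded by default because no counting rule exists for
them — `StudyConfig.include_mci` folds them into the affected cell for
sensitivity analyses.

Two strict-inequality rules excuse apparent failures of dominant
segregation:

* phenocopy: affected non-carrier with AAO > mean AAO of the family's
  affected carriers (additive margin `phenocopy_margin`, default 0 —
  onset exactly at the carrier mean is *not* excused). Late-onset
  dementia is common enough that densely affected families are expected
  to contain sporadic cases.
* presymptomatic carrier: unaffected carrier with age at last
  evaluation < the family's oldest affected-carrier onset. Such a
  carrier has not yet outlived the family's observed onset range.

Both rules anchor on the family's own affected carriers (per-family, not
pooled across families sharing the variant); with a single affected
carrier its onset is both mean and maximum. A family with fewer than
`min_informative` (default 2) genotyped affected members is
UNINFORMATIVE — the threshold is a package choice, since the reference
analysis only states that small sampled families were inconclusive.
A family is NON_SEGREGATING as soon as one affected non-carrier or one
unaffected carrier is left unexcused. We deliberately do **not** treat
affected non-carriers outnumbering affected carriers as non-segregation
per se: a family in which one genotyped affected carries a known
pathogenic nonsense variant while three much-later-onset affected
relatives do not is informatively compatible with phenocopies, and the
reference analysis treats it as such.

No likelihood-based co-segregation statistic (LOD score, Bayes factor)
is computed; the procedure is intentionally the rule-based one.

## Classification cascade

First match wins:

1. database-pathogenic and no NON_SEGREGATING family → PATHOGENIC;
2. all families PERFECT/COMPATIBLE, zero carriers in control-role
   cohorts, and a damaging prediction (or splice-score loss: wild type
   ≥ 0.8 and mutant < 0.2, an operationalisation of a 1.00 → 0.00
   score collapse) → LIKELY_PATHOGENIC if novel, PATHOGENIC if
   previously reported. This step overrides a prior "not pathogenic"
   database label: a variant previously dismissed for appearing in a few
   unaffected individuals can still be a reduced-penetrance allele if it
   segregates perfectly and is absent from thousands of controls;
3. any NON_SEGREGATING family or any control carrier → NOT_PATHOGENIC,
   with a candidate-modifier annotation (not a fifth category) when the
   case frequency still exceeds the control frequency;
4. otherwise UNKNOWN.

Unselected population panels do not count as controls by default: a
panel with mean exam age ~52 y cannot exclude late-onset disease
carriers. `count_unselected_as_controls` flips this.

The packaged classification table additionally carries the *published*
cell assignments, which the tabulation stage reproduces verbatim. The
published table is not everywhere derivable from the cascade (several
previously reported variants sit in its "pathogenicity unknown" column
even though they failed segregation and appeared in controls), so
fixture comparisons pin the printed assignments while `classify_variant`
implements the cascade.

## Burden statistics

Collapsing sums carriers of any selected variant per named cohort;
denominators are cohort sizes, never sums over variants, and a cohort
name with inconsistent sizes is a hard error. The 2×2 summary reports
the cross-product OR, a Woolf (log-normal) 95% CI, a two-sided Fisher
exact p (primary — expected cells are small for rare variants) and the
Pearson chi-square without continuity correction, side by side. When a
cell is zero, Haldane–Anscombe +0.5 is applied to all cells for the OR
and CI only, and flagged. No multiple-testing adjustment is applied
anywhere, matching the reference analysis; reports say so. Published
CIs were produced with an unstated method and are not always
Woolf-consistent, so the OR — not the CI — is the comparison surface.

## Onset models

Affected individuals contribute AAO as an event; unaffected contribute
age at last evaluation as right-censored. Kaplan–Meier curves and the
standard log-rank chi-square ignore family clustering: the reference
analysis used proportional-hazards models with family and sex terms,
which require individual-level data never released; the marginal
contrast is a documented simplification, not an estimate of the same
quantity. Mean-onset contrasts report Welch-t and Wilcoxon p together.

The carrier-predictor logistic model (one record per family: reported
affected count, proband AAO, sex, APOE4 dose) is fitted by maximum
likelihood, with a forward-only stepwise option entering covariates by
Rao score test at p < 0.05. Separation falls back to a lightly
penalised fit, flagged in the model notes. Reported per-unit odds
ratios follow field conventions (per 2 affected relatives, per 5 years
of onset). ROC/AUC uses midrank tie handling, so AUC equals the
Mann–Whitney normalisation exactly.

## Synthetic families

The simulator generates two founders, a sibship of children (uniform
2–6) with married-in spouses, and grandchildren; one founder introduces
the causal allele and transmission is Mendelian. Parameters and
defaults:

| parameter | default | meaning |
|---|---|---|
| `affected_count_histogram` | reference histogram (439 families, mean 5.78) | reported affected per family |
| `family_mean_onset_mean/sd` | 72.80 / 5.62 y | family-mean AAO distribution, truncated 60–89 |
| `within_family_aao_sd` | 6.2 y | individual scatter; √(8.37² − 5.62²), decomposing the cohort's marginal AAO sd into between- and within-family parts |
| `penetrance_location/scale` | 72 / 5 y | logistic age-dependent penetrance (~93% by 85) |
| `phenocopy_rate` | 0.05 | expected affected non-carriers **per family** (Poisson) |
| `censor_age_range` | 55–85 y | exam-age range of the middle generation |
| `apoe4_allele_freq` | 0.7213 | allele frequency among familial cases |
| `apoe4_onset_shift` | 3 y/allele | earlier onset per ε4 allele, centred on the expected dose so the marginal mean is preserved |

Affection for carriers is Bernoulli in the penetrance at the member's
exam age; onsets are then drawn from the family-centred normal
(truncated 30–92). Unaffected members record the same exam age used by
the penetrance draw as their censoring age, so presymptomatic carriers
are internally consistent. The *reported* affected count is drawn from
the histogram and floored at the sampled affected count, emulating
family-history reports that exceed the sampled pedigree.

What the generator does **not** emulate: within-family Mendelian APOE
transmission (alleles are drawn marginally), assortative censoring,
competing mortality, diagnostic misclassification, and onset ages
constrained by the assessment age for affected members (the assessment
age gates affection only; onset is reported retrospectively). Passing
validation therefore shows the pipeline recovers truth under a clean
dominant-with-phenocopies model — not that it is robust to the full
messiness of real family data.

## Validation quantities and problem sizes

The acceptance script and tests use desk-scale sizes chosen to keep the
whole suite in the low minutes on one CPU: 2,000 replicates for the
exact-test type-I error at the null (439 cases / 1,346 controls at 3%
carrier frequency), 500 replicates for odds-ratio recovery (6.4% vs
3.0% at 439 / 12,481; true OR 2.21), 200 simulated families for the
classification confusion matrix in a high-penetrance regime (penetrance
location 60, scale 4; ~95% penetrant at typical censoring ages;
phenocopy rate 0.05), and 100 families for the full-penetrance
perfect-segregation property. Published quantities that require
individual-level data (AAO contrasts such as 67.8 vs 70.5 y, the
per-variant onset shifts, logistic ORs 1.33/0.807, AUC 0.6022, the
APOE4-dose survival curves) are demonstration outputs on synthetic data
only and are not comparison surfaces.

## Numerical conventions

Means/sds use ddof = 1 and are absent below n = 2. Percentages are
rounded to the destination table's convention (1 d.p. for summary-table
cells, 2–3 d.p. for text-style frequencies), ORs to 2 d.p.; all are
recomputed from counts. The normal quantile 1.959964 is used for 95%
intervals. Ties in ROC scoring are midranked; simultaneous survival
events are handled by the product-limit convention. All randomness runs
through `numpy.random.default_rng` with explicit seeds; identical
config + seed reproduces byte-identical outputs.
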