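# Methods

## The phenotype definitions

`trdpheno` derives two phenotypes per patient from dated primary-care
records: major depressive disorder (MDD) status and, among treated MDD
cases, treatment-resistant depression (TRD).

**MDD.** A patient is a *case* when they carry at least two depression
diagnostic codes on distinct dates (the two-code rule guards against a
single miscoded entry; the distinct-dates requirement additionally guards
against same-day duplicate coding) and carry no bipolar, psychotic or
substance-use code at any time — depression in those contexts has a
different clinical and genetic profile, so such patients are *excluded*.
A *control* carries no psychiatric code of any category. Every other
patient — one depression code only, or non-depression psychiatric coding —
belongs to neither the case nor the control set and is reported as
`EXCLUDED`; the enum folds "excluded by diagnosis" and "excluded as neither
case nor clean control" into one analysis-exclusion label. Two switches
relax this: `min_depression_codes=1` reproduces the more liberal one-code
case definition, and `control_screening="mdd_only"` screens controls for
depression codes only (both exist to support sensitivity analyses of the
primary definition).

**Drug episodes and switches.** Prescriptions of the same antidepressant
are chained into an episode while consecutive issues are ≤ 98 days
(14 weeks) apart; a larger gap starts a new episode. Episode duration is
last minus first issue date, so a single prescription has duration 0. An
episode *qualifies* for switch logic when it spans ≥ 42 days (6 weeks) —
a deliberately conservative margin over the ~4 weeks needed to judge
efficacy, reducing the chance that a recorded switch reflects early
side-effects. A *switch* is an adjacent pair of qualifying episodes of
different antidepressants (class is irrelevant) whose between-episode gap
is ≤ 98 days (treatment was not simply suspended) and whose date ranges
overlap by ≤ 30 days. **TRD** = MDD case, at least one antidepressant
prescription, and ≥ 2 switches.

Three boundary decisions are genuinely open in this kind of rule set and
are fixed here as explicit, configurable defaults:

- *Within-drug chaining gap*: the same 98-day limit as the between-drug
  rule, applying one notion of "treatment not suspended" uniformly.
- *A→B→A*: two switches. Each switch constrains only the two adjacent
  drugs; drug novelty is not required.
- *Concurrency carve-out*: episode pairs overlapping > 30 days are
  combinations (an explicit TRD treatment strategy, analysed separately via
  `combination_flag`) and are not counted as switches, since a switch
  implies discontinuation. Augmentation (`augmentation_flag`) is the same
  > 30-day overlap test between an antidepressant episode and an
  antipsychotic or mood-stabilizer episode.

All interval arithmetic is in whole days with inclusive comparisons
(42 and 98 days exactly; a 98-day gap still chains, a 99-day gap splits).

**Adherence proxy.** The proportion of *adequate* intervals — ≤ 98 days
between consecutive antidepressant prescriptions, pooling all drugs — is
reported per patient. It deliberately differs from the switch rules (every
consecutive interval counts, not only between-drug transitions), so it is
not circular with the TRD definition. It is missing with < 2 prescriptions.

**Record density.** Per-patient totals and distinct-date counts of clinical
and prescription records, and rates per year of observation, where the span
is (last − first record date)/365.25 floored at 1 year so single-day
records yield finite rates.

## Statistical layer

- **Prevalence** is reported as a percentage at 2 decimal places.
- **Odds ratios** for 2×2 tables use ad/(bc) with the Woolf log-normal 95%
  interval, SE = √(1/a+1/b+1/c+1/d); zero cells receive the
  Haldane–Anscombe 0.5 correction and are flagged. Equality with the
  exponentiated coefficient of an intercept-plus-exposure logistic fit is a
  test invariant, not an implementation detail.
- **Polygenic scores** are weighted allele-dosage sums over SNPs passing a
  discovery p-value threshold P_T, standardized across the cohort. The
  default grid {5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0}
  holds 11 thresholds and is configurable; the "most predictive" P_T
  maximizes incremental Nagelkerke R² (ties break toward the smaller
  threshold, a deterministic rule). LD clumping is replaced by the
  assumption of independent SNPs, which is true of the synthetic genotypes.
- **Association** is a maximum-likelihood logistic regression of case
  status on the score plus covariates; the reported R² is the Nagelkerke
  rescaling of the Cox–Snell R² of the full versus covariate-only model
  (the PRS-literature convention of incremental R² over covariates), with
  the Nagelkerke maximum taken from the intercept-only likelihood.
  Separation or a constant score is flagged in the result rather than
  raised.
- **Liability-scale conversions** use the liability-threshold model: with
  population prevalence K, threshold t = Φ⁻¹(1−K), density z = φ(t) and
  sample case proportion P,
  h²_liab = h²_obs · K²(1−K)² / (z² · P(1−P)) (and its inverse), and for
  polygenic-score R² the ascertainment-corrected Lee (2012) form
  R²_liab = C·R²_obs / (1 + C·θ·R²_obs) with C = K²(1−K)²/(z²·P(1−P)) and
  θ = m·(P−K)/(1−K) · (m·(P−K)/(1−K) − t), m = z/K. With P = K the
  correction reduces to the plain K(1−K)/z² rescaling. t and z are always
  recomputed from K, never cached. Both transforms are validated against an
  independent oracle that derives t by bisection on the normal CDF and z by
  central differencing.
- **Effect comparisons** between two samples use
  z = (β₁−β₂)/√(SE₁²+SE₂²) with a two-sided normal p. Tail probabilities
  use the complementary survival function; where the p-value would
  underflow float64 (|z| ≳ 38.5) it is exponentiated from the log survival
  function in extended precision, so p stays positive through |z| = 40.
- **Multiple testing** is Bonferroni (α/n over traits × thresholds), and
  cross-measure agreement of two binary depression measures is
  100·|A∩B|/|A| with pairwise deletion of missing values.

## The synthetic-data generator

The generator emulates the *structure* the phenotyping rules must
discriminate, not real primary care. Each patient draws a trajectory
archetype: `UNTREATED`, `SINGLE_DRUG`, `SWITCHER` (three qualifying
episodes of different antidepressants with ≤ 98-day gaps — planted TRD),
`COMBINATION` (two antidepressants overlapping > 30 days) or `NONADHERENT`
(one drug with a planted > 98-day gap). Planted MDD cases receive ≥ 2
depression codes on distinct dates before any prescription (mirroring
diagnose-then-treat ordering without claiming to model onset); planted
excluded patients additionally receive an exclusion code; every patient
receives 1–3 non-psychiatric codes so each has a primary-care record.

Defaults define the study conditions: 10% MDD prevalence (near the 10.8%
lifetime estimate for the UK population), 80% of cases treated, 13% of
treated cases on a switcher trajectory (the TRD share of treated
primary-care MDD cases reported in large UK cohorts), 5% exclusion diagnoses, 8%
combination and 5% augmentation trajectories, 10% non-adherent, and a
28 ± 7-day prescribing rhythm over a 2000–2015 window.

Numerical choices worth knowing:

- *Intervals* are mean ± uniform jitter, truncated into [1, 98] days; the
  truncation at 98 means jitter can never fragment a planted episode, so
  the only > 98-day gaps are the planted non-adherence ones. Episodes issue
  scripts until their span reaches 42 days, so with a 21-day interval and
  zero jitter episodes span *exactly* 42 days — the configuration used to
  demonstrate rule sensitivity (a 42→43-day rule change flips every planted
  TRD label).
- *Stratum sizes* are deterministic rounded counts (round(fraction·n));
  seeded shuffles decide which patients fall in each stratum. Configured
  prevalences are therefore recovered exactly up to rounding rather than
  with binomial noise, which is what makes "noise-free recovery equals the
  configured fraction exactly" a testable contract.
- *Genetics*: independent SNPs with allele frequencies uniform in the MAF
  range, dosages binomial(2, f); liability = √h²·(standardized additive
  score) + √(1−h²)·noise, and the round(K·n) highest liabilities are cases.
  When genotypes accompany a cohort, planted MDD cases are exactly the
  top-liability patients, tying case status to genotype with the configured
  h². Sub-streams for assignment, coding and prescribing are spawned from
  the master seed, so components are individually reproducible.

What the generator does **not** model — and what passing tests therefore do
not show about real data: no real Read/CTV3 vocabularies (an illustrative
codelist ships for pipeline exercises; real codelists are user input), no
dose or quantity information, no comorbidity structure, no calendar-time
prescribing trends beyond uniform placement, no LD between SNPs, no
population stratification, and no informative missingness. Perfect
noise-free label recovery demonstrates that the implementation applies the
stated rules exactly; it says nothing about the rules' clinical validity in
real records, which can only be assessed against external measures of
depression as in the motivating studies.

## Problem sizes

The default test and acceptance workloads use cohorts of 2,000–10,000
patients, 50–500 SNPs, a 20,000 × 500 liability simulation for the
variance-recovery check, and 200–500 replicates for the calibration checks;
these sizes put Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run under a minute on one core.

## Known limitations

- The discovery-GWAS stand-in (per-SNP allelic 2×2 statistics) is noisy at
  small cohort sizes, so pipeline PRS associations at n ≈ 2,000 are weak;
  the calibration and recovery checks therefore use direct simulation at
  larger n.
- `EXCLUDED` conflates exclusion diagnoses with subthreshold depression
  coding; consumers needing the distinction should re-derive it from
  `classify_mdd` inputs.
- The within-drug 98-day chaining gap and the 30-day concurrency carve-out
  are this package's explicit operationalisations of choices that published
  rule sets leave implicit; both are parameters, not constants.
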