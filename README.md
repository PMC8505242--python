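# trdpheno

Phenotyping of **major depressive disorder (MDD)** and
**treatment-resistant depression (TRD)** from primary-care electronic
health records, for epidemiologists and psychiatric-genetics researchers
working with UK-style GP extracts (dated Read v2 / CTV3 clinical codes and
prescription issues).

TRD — failure to respond to successive adequate antidepressant trials — is
invisible to questionnaires and hospital codes but can be read off
longitudinal prescribing records. `trdpheno` implements the rule set as a
tested, reusable pipeline, together with the statistical layer used around
it and a synthetic-cohort simulator so that every stage is verifiable
without access-controlled patient data.

## The algorithm

Per patient:

- **MDD case**: ≥ 2 depression diagnostic codes on distinct dates, and no
  bipolar, psychotic or substance-use code at any time. Controls carry no
  psychiatric code; everyone else is excluded from both sets.
- **Drug episode**: maximal run of same-drug prescriptions with consecutive
  gaps ≤ 98 days (14 weeks); duration = last − first issue date. An episode
  qualifies for switch logic when it spans ≥ 42 days (6 weeks).
- **Switch**: adjacent qualifying episodes of different antidepressants
  with a between-episode gap ≤ 98 days and date-range overlap ≤ 30 days
  (longer overlap is a *combination*, not a switch).
- **TRD**: MDD case with ≥ 1 antidepressant prescription and **≥ 2
  switches**.
- Adjuncts: an adherence proxy (share of consecutive antidepressant
  intervals ≤ 98 days, pooling drugs), combination/augmentation flags
  (> 30-day overlaps), record-density summaries and annual prescribing
  trends.

The statistical layer provides prevalences, 2×2 odds ratios (Woolf CI,
Haldane–Anscombe correction), polygenic risk scores over a grid of 11
p-value thresholds with logistic association and incremental Nagelkerke R²,
liability-scale transformations of case-control h² and PRS R²
(h²_liab = h²_obs·K²(1−K)²/(z²P(1−P)); Lee 2012 ascertainment correction
for R²), two-sample z-tests of effect sizes, Bonferroni correction and
binary-measure overlap. See `docs/methods.md` for the full model notes.

## Worked example

```python
from trdpheno import RunConfig, run_pipeline

cfg = RunConfig.from_dict({"n_patients": 2000, "seed": 42})
res = run_pipeline(cfg)
print(res.report)
```

prints (abridged):

```
## Cohort flow and prevalence

- patients with records: 2000
- excluded (exclusion diagnosis or subthreshold coding): 100
- MDD cases: 200 (10.0%)
- treated MDD cases: 160
- TRD: 21 (13.12% of treated cases)
```

The simulated cohort planted 10% MDD prevalence and a 13% switcher fraction
among the 160 treated cases; phenotyping recovers 200/2000 cases (10.0%)
and 21/160 TRD (13.12% — round(0.13·160) = 21 planted switchers, every one
detected). The report continues with the TRD vs non-TRD comparison table
(combination, augmentation and adherence-proxy odds ratios with
Bonferroni-adjusted α) and, when genotypes are simulated, the PRS
association across thresholds with observed- and liability-scale R².

The same stages are available from the shell:

```sh
trdpheno simulate  --out-dir sim --seed 42
trdpheno phenotype --clinical sim/clinical.csv --scripts sim/prescriptions.csv \
                   --codelist-dx sim/codelist_dx.csv --codelist-rx sim/codelist_rx.csv \
                   --out phenotypes.csv
trdpheno stats     --phenotypes phenotypes.csv --out stats/
trdpheno run       --out-dir out --seed 42     # all of the above + report
```

Real extracts drop in the same way: the readers expect
`patient_id,event_dt,read_2,read_3` and `patient_id,issue_date,drug_name,raw_code`
tables with ISO dates, plus user-supplied codelists mapping codes to
diagnostic categories and drug-name patterns to substances and classes.

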