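"""Synthetic primary-care cohorts with planted MDD/TRD structure.

The generator emits the same two tables the phenotyping algorithm consumes —
dated diagnostic codes and antidepressant prescriptions — plus simulated
genotypes under a liability-threshold genetic model and a truth table of the
planted labels.  Every downstream stage of the pipeline is therefore testable
with no external data: phenotype recovery against planted labels, prevalence
recovery, and liability-scale transformations against the generating model.

Patients are assigned trajectory archetypes that encode the treatment
patterns the phenotyping rules must discriminate:

- ``UNTREATED``     no prescriptions;
- ``SINGLE_DRUG``   one qualifying episode (>= 42-day span) of one drug;
- ``SWITCHER``      three qualifying episodes of different antidepressants
                    separated by gaps <= 98 days (planted TRD);
- ``COMBINATION``   two antidepressants overlapping by > 30 days;
- ``NONADHERENT``   one drug with a planted > 98-day gap in its scripts.

Within-episode intervals are drawn as ``interval_mean_days`` plus uniform
jitter, truncated into [1, 98] days so a planted episode can never fragment
by accident; the planted non-adherence gap is the only way a > 98-day gap
arises.  Stratum sizes are deterministic rounded counts (seeded shuffles
decide *which* patients), so configured prevalences are recovered exactly up
to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_core import (
    ClinicalEvent,
    Codelist,
    CodeSystem,
    DiagnosisCategory,
    DrugClass,
    PrescriptionEvent,
    example_codelist,
    write_clinical_table,
    write_prescription_table,
)
from .phenotyping import COMBINATION_OVERLAP_DAYS, MAX_GAP_DAYS, MIN_EPISODE_DAYS


class Archetype(str, Enum):
    UNTREATED = "UNTREATED"
    SINGLE_DRUG = "SINGLE_DRUG"
    SWITCHER = "SWITCHER"
    COMBINATION = "COMBINATION"
    NONADHERENT = "NONADHERENT"


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the simulated cohort.

    Defaults emulate UK primary-care depression epidemiology: lifetime MDD
    prevalence near 10%, most cases treated, and roughly 13% of treated
    cases following a switcher (treatment-resistant) trajectory, with a
    monthly prescribing rhythm.
    """

    n_patients: int = 2000
    mdd_prevalence: float = 0.10
    treated_fraction: float = 0.80
    trd_fraction: float = 0.13
    exclusion_rate: float = 0.05
    interval_mean_days: float = 28.0
    interval_jitter_days: float = 7.0
    nonadherent_fraction: float = 0.10
    combination_rate: float = 0.08
    augmentation_rate: float = 0.05
    start_year: int = 2000
    n_years: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.interval_mean_days <= 0:
            raise ValueError("interval_mean_days must be positive")
        for name in (
            "mdd_prevalence", "treated_fraction", "trd_fraction", "exclusion_rate",
            "nonadherent_fraction", "combination_rate", "augmentation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mdd_prevalence + self.exclusion_rate > 1.0:
            raise ValueError("mdd_prevalence + exclusion_rate exceed 1")
        if self.trd_fraction + self.nonadherent_fraction + self.combination_rate > 1.0:
            raise ValueError("treated-archetype fractions exceed 1")


@dataclass(frozen=True)
class GeneticConfig:
    """Liability-threshold genetic model: ``h2_liability`` of the liability
    variance is an additive score over ``n_snps`` independent SNPs with
    allele frequencies uniform in ``maf_range``; disease corresponds to
    liability above the (1 - K) quantile."""

    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_liability: float = 0.3
    prevalence_k: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be a non-empty interval within (0, 0.5]")
        if not 0.0 <= self.h2_liability < 1.0:
            raise ValueError("h2_liability must be in [0, 1)")
        if not 0.0 < self.prevalence_k < 1.0:
            raise ValueError("prevalence_k must be in (0, 1)")


# -- genetics --------------------------------------------------------------


def simulate_genotypes(gc: GeneticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw a patients x SNPs dosage matrix (0/1/2), binomial in per-SNP
    allele frequencies sampled uniformly in ``maf_range``.

    The number of patients is taken from a companion cohort via
    :func:`generate_cohort`; called standalone it uses 2 * n_snps patients.
    """
    return _simulate_genotypes(gc, n_patients=2 * gc.n_snps,
                               rng=np.random.default_rng(gc.seed))


def _simulate_genotypes(
    gc: GeneticConfig, n_patients: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    freqs = rng.uniform(gc.maf_range[0], gc.maf_range[1], size=gc.n_snps)
    dosages = rng.binomial(2, freqs, size=(n_patients, gc.n_snps))
    return dosages.astype(np.int8), freqs


@dataclass
class LiabilitySim:
    """Realized liabilities and case labels plus the generating SNP weights
    (the "true" polygenic weights used in recovery checks)."""

    case: np.ndarray
    liability: np.ndarray
    genetic_value: np.ndarray
    snp_weights: np.ndarray


def simulate_liability_case_control(
    genotypes: np.ndarray, gc: GeneticConfig, rng: np.random.Generator | None = None
) -> LiabilitySim:
    """Simulate case/control status under the liability-threshold model.

    liability = sqrt(h2) * standardized additive score + sqrt(1-h2) * noise;
    the round(K*n) patients with the highest realized liability are cases, so
    the realized case fraction matches K up to rounding.  With h2 = 0 case
    status is independent of genotype.
    """
    if rng is None:
        rng = np.random.default_rng(gc.seed + 1)
    geno = np.asarray(genotypes, dtype=float)
    n = geno.shape[0]
    weights = rng.standard_normal(geno.shape[1])
    raw = geno @ weights
    sd = raw.std(ddof=0)
    g = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    h2 = gc.h2_liability
    liability = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * rng.standard_normal(n)
    n_cases = int(round(gc.prevalence_k * n))
    case = np.zeros(n, dtype=bool)
    if n_cases > 0:
        case[np.argsort(-liability, kind="stable")[:n_cases]] = True
    return LiabilitySim(case=case, liability=liability, genetic_value=g, snp_weights=weights)


# -- prescribing trajectories ----------------------------------------------


def _interval(cfg: CohortConfig, rng: np.random.Generator) -> int:
    raw = cfg.interval_mean_days + rng.uniform(
        -cfg.interval_jitter_days, cfg.interval_jitter_days
    )
    return int(min(MAX_GAP_DAYS, max(1, round(raw))))


def _episode_dates(
    start: date, cfg: CohortConfig, rng: np.random.Generator
) -> list[date]:
    """Prescription dates of one qualifying episode: scripts at jittered
    intervals until the span reaches the 42-day qualifying threshold."""
    dates = [start]
    while (dates[-1] - start).days < MIN_EPISODE_DAYS:
        dates.append(dates[-1] + timedelta(days=_interval(cfg, rng)))
    return dates


def _make_rx(pid: str, d: date, drug: str, drug_class: DrugClass) -> PrescriptionEvent:
    return PrescriptionEvent(pid, d, drug, drug_class)


def simulate_prescription_history(
    archetype: Archetype,
    config: CohortConfig,
    seed: int | np.random.Generator,
    patient_id: str = "P1",
    start_date: date = date(2005, 1, 6),
    drugs: list[str] | None = None,
) -> list[PrescriptionEvent]:
    """Emit one patient's antidepressant prescription history for a
    trajectory archetype (see module docstring for the patterns)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if drugs is None:
        drugs = ["citalopram", "sertraline", "mirtazapine"]
    events: list[PrescriptionEvent] = []
    if archetype is Archetype.UNTREATED:
        return events
    if archetype is Archetype.SWITCHER:
        t = start_date
        for drug in drugs[:3]:
            ep = _episode_dates(t, config, rng)
            events += [_make_rx(patient_id, d, drug, DrugClass.ANTIDEPRESSANT) for d in ep]
            t = ep[-1] + timedelta(days=_interval(config, rng))
    elif archetype is Archetype.COMBINATION:
        ep_a = _episode_dates(start_date, config, rng)
        # second drug starts 7 days in: both episodes qualify (>= 42-day span)
        # so the overlap is at least 35 days, above the 30-day combination bar
        ep_b = _episode_dates(start_date + timedelta(days=7), config, rng)
        events += [_make_rx(patient_id, d, drugs[0], DrugClass.ANTIDEPRESSANT) for d in ep_a]
        events += [_make_rx(patient_id, d, drugs[1], DrugClass.ANTIDEPRESSANT) for d in ep_b]
    elif archetype is Archetype.NONADHERENT:
        ep = _episode_dates(start_date, config, rng)
        events += [_make_rx(patient_id, d, drugs[0], DrugClass.ANTIDEPRESSANT) for d in ep]
        # planted inadequate interval: strictly beyond the 98-day rule
        resume = ep[-1] + timedelta(days=MAX_GAP_DAYS + max(1, round(config.interval_mean_days)))
        events.append(_make_rx(patient_id, resume, drugs[0], DrugClass.ANTIDEPRESSANT))
        events.append(
            _make_rx(
                patient_id,
                resume + timedelta(days=_interval(config, rng)),
                drugs[0],
                DrugClass.ANTIDEPRESSANT,
            )
        )
    else:  # SINGLE_DRUG
        ep = _episode_dates(start_date, config, rng)
        events += [_make_rx(patient_id, d, drugs[0], DrugClass.ANTIDEPRESSANT) for d in ep]
    events.sort(key=lambda e: (e.issue_date, e.drug_id))
    return events


def _augmentation_history(
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str,
    ad_events: list[PrescriptionEvent],
    drug: str,
    drug_class: DrugClass,
) -> list[PrescriptionEvent]:
    """Add-on antipsychotic/mood-stabilizer episode overlapping the first
    antidepressant episode by construction (> 30 days)."""
    start = min(e.issue_date for e in ad_events) + timedelta(days=5)
    return [_make_rx(patient_id, d, drug, drug_class) for d in _episode_dates(start, config, rng)]


# -- cohort assembly -------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Generated tables plus the planted truth used for recovery testing."""

    clinical_events: list[ClinicalEvent]
    prescription_events: list[PrescriptionEvent]
    genotypes: np.ndarray | None
    allele_freqs: np.ndarray | None
    snp_weights: np.ndarray | None
    truth: pd.DataFrame
    codelist: Codelist = field(default_factory=example_codelist)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_clinical_table(self.clinical_events, out / "clinical.csv")
        write_prescription_table(self.prescription_events, out / "prescriptions.csv")
        self.truth.to_csv(out / "truth.csv", index=False)
        self.codelist.to_files(out / "codelist_dx.csv", out / "codelist_rx.csv")
        if self.genotypes is not None:
            np.savetxt(out / "genotypes.tsv", self.genotypes, fmt="%d", delimiter="\t")
            np.savetxt(out / "allele_freqs.tsv", self.allele_freqs, delimiter="\t")
            np.savetxt(out / "snp_weights.tsv", self.snp_weights, delimiter="\t")


def _deterministic_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def generate_cohort(
    cohort_config: CohortConfig, genetic_config: GeneticConfig | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    Patients with planted MDD receive >= 2 depression codes on distinct dates
    placed before any prescription; excluded patients additionally receive a
    bipolar/psychotic/substance-use code; everyone receives at least one
    non-psychiatric code so each patient has a primary-care record.  When a
    genetic model is supplied, planted MDD cases are the patients with the
    highest realized liabilities, tying case status to genotype.
    """
    cfg = cohort_config
    n = cfg.n_patients
    codelist = example_codelist()
    master = np.random.SeedSequence(cfg.seed)
    # independent sub-streams: assignment, clinical coding, prescribing
    rng_assign, rng_clin, rng_rx = (np.random.default_rng(s) for s in master.spawn(3))

    patient_ids = [f"P{i:06d}" for i in range(n)]
    window_start = date(cfg.start_year, 1, 1)
    window_days = int(cfg.n_years * 365.25)

    genotypes = allele_freqs = snp_weights = None
    liability = np.full(n, np.nan)
    if genetic_config is not None and genetic_config.n_snps > 0 and n > 0:
        rng_gen = np.random.default_rng(genetic_config.seed + 100003)
        genotypes, allele_freqs = _simulate_genotypes(genetic_config, n, rng_gen)
        gc = replace(genetic_config, prevalence_k=min(max(cfg.mdd_prevalence, 1e-9), 1 - 1e-9))
        sim = simulate_liability_case_control(genotypes, gc, rng_gen)
        liability = sim.liability
        snp_weights = sim.snp_weights

    n_mdd = _deterministic_count(cfg.mdd_prevalence, n)
    n_excl = _deterministic_count(cfg.exclusion_rate, n)
    if np.isnan(liability).all():
        order = rng_assign.permutation(n)
    else:
        order = np.argsort(-liability, kind="stable")
    mdd_idx = list(order[:n_mdd])
    rest = list(order[n_mdd:])
    rng_assign.shuffle(rest)
    excl_idx = set(rest[:n_excl])
    mdd_set = set(mdd_idx)

    # treated-archetype assignment among planted MDD cases
    n_treated = _deterministic_count(cfg.treated_fraction, n_mdd)
    treated_order = list(mdd_idx)
    rng_assign.shuffle(treated_order)
    treated = treated_order[:n_treated]
    n_trd = _deterministic_count(cfg.trd_fraction, n_treated)
    n_nonadh = _deterministic_count(cfg.nonadherent_fraction, n_treated)
    n_comb = _deterministic_count(cfg.combination_rate, n_treated)
    if n_trd + n_nonadh + n_comb > n_treated:
        raise ValueError("treated-archetype counts exceed the treated stratum")
    archetype: dict[int, Archetype] = {i: Archetype.UNTREATED for i in range(n)}
    for i, idx in enumerate(treated):
        if i < n_trd:
            archetype[idx] = Archetype.SWITCHER
        elif i < n_trd + n_nonadh:
            archetype[idx] = Archetype.NONADHERENT
        elif i < n_trd + n_nonadh + n_comb:
            archetype[idx] = Archetype.COMBINATION
        else:
            archetype[idx] = Archetype.SINGLE_DRUG
    n_aug = _deterministic_count(cfg.augmentation_rate, n_treated)
    augmented = set(treated[:0] if n_aug == 0 else
                    rng_assign.choice(treated, size=n_aug, replace=False).tolist())

    depression_codes = [c for c, cat in codelist.diagnosis_map.items()
                        if cat is DiagnosisCategory.DEPRESSION]
    exclusion_codes = [c for c, cat in codelist.diagnosis_map.items()
                       if cat in (DiagnosisCategory.BIPOLAR, DiagnosisCategory.PSYCHOTIC,
                                  DiagnosisCategory.SUBSTANCE_USE)]
    neutral_codes = [c for c, cat in codelist.diagnosis_map.items()
                     if cat is DiagnosisCategory.NON_PSYCHIATRIC]
    ad_drugs = sorted(d for d, (_, k) in codelist.drug_map.items()
                      if k is DrugClass.ANTIDEPRESSANT)
    adjunct_drugs = sorted((d, k) for d, (_, k) in codelist.drug_map.items()
                           if k in (DrugClass.ANTIPSYCHOTIC, DrugClass.MOOD_STABILIZER))

    clinical: list[ClinicalEvent] = []
    prescriptions: list[PrescriptionEvent] = []
    truth_rows = []
    for idx in range(n):
        pid = patient_ids[idx]
        is_mdd = idx in mdd_set
        is_excl = idx in excl_idx
        arch = archetype[idx]
        # anchor: treatment start (and reference point for diagnosis codes),
        # kept a year inside the window so pre-treatment codes fit
        anchor = window_start + timedelta(
            days=int(rng_clin.integers(366, max(367, window_days - 366)))
        )
        if is_mdd or is_excl:
            # two depression codes on distinct dates, before any prescription
            d1 = anchor - timedelta(days=int(rng_clin.integers(180, 365)))
            d2 = anchor - timedelta(days=int(rng_clin.integers(7, 180)))
            for d in (d1, d2):
                clinical.append(
                    ClinicalEvent(pid, d, str(rng_clin.choice(depression_codes)), CodeSystem.READ2)
                )
        if is_excl:
            d3 = anchor - timedelta(days=int(rng_clin.integers(1, 7)))
            clinical.append(
                ClinicalEvent(pid, d3, str(rng_clin.choice(exclusion_codes)), CodeSystem.READ2)
            )
        for _ in range(int(rng_clin.integers(1, 4))):  # everyone has GP contact
            d = window_start + timedelta(days=int(rng_clin.integers(0, window_days)))
            clinical.append(
                ClinicalEvent(pid, d, str(rng_clin.choice(neutral_codes)), CodeSystem.READ2)
            )
        if is_mdd and arch is not Archetype.UNTREATED:
            drugs = [str(x) for x in rng_rx.choice(ad_drugs, size=3, replace=False)]
            history = simulate_prescription_history(arch, cfg, rng_rx, pid, anchor, drugs)
            prescriptions += history
            if idx in augmented and history:
                drug, kls = adjunct_drugs[int(rng_rx.integers(len(adjunct_drugs)))]
                prescriptions += _augmentation_history(cfg, rng_rx, pid, history, drug, kls)
        truth_rows.append(
            {
                "patient_id": pid,
                "true_mdd": is_mdd,
                "true_trd": arch is Archetype.SWITCHER,
                "true_excluded": is_excl,
                "genetic_liability": liability[idx] if n else np.nan,
                "trajectory_archetype": arch.value,
            }
        )

    clinical.sort(key=lambda e: (e.patient_id, e.event_date, e.code))
    prescriptions.sort(key=lambda e: (e.patient_id, e.issue_date, e.drug_id))
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "true_mdd", "true_trd", "true_excluded",
                 "genetic_liability", "trajectory_archetype"],
    )
    return SyntheticCohort(
        clinical_events=clinical,
        prescription_events=prescriptions,
        genotypes=genotypes,
        allele_freqs=allele_freqs,
        snp_weights=snp_weights,
        truth=truth,
        codelist=codelist,
    )
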