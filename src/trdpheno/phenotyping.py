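"""EHR phenotyping of major depressive disorder (MDD) and treatment-resistant
depression (TRD) from dated diagnostic and prescribing records.

The algorithm, applied per patient:

1. **MDD status** — CASE requires at least ``min_depression_codes`` (default 2)
   depression diagnostic codes on distinct dates and no bipolar / psychotic /
   substance-use code at any time.  Patients with an exclusion code, or with
   psychiatric codes that fall short of the case definition (e.g. a single
   depression code), are EXCLUDED from both case and control sets; CONTROL
   means no psychiatric code at all (optionally relaxed to "no depression
   code" for sensitivity analyses).
2. **Drug episodes** — per antidepressant, consecutive prescriptions no more
   than 98 days (14 weeks) apart are chained into an episode; episode
   duration is last minus first issue date.  An episode *qualifies* for the
   switch logic when it spans at least 42 days (6 weeks), a conservative
   margin over the 4 weeks considered adequate for efficacy, so that a switch
   is less likely to reflect early side-effects.
3. **Switches** — adjacent qualifying episodes of *different* antidepressants
   with a between-episode gap of at most 98 days count as a switch, unless
   their date ranges overlap by more than 30 days (that is a combination, a
   distinct treatment strategy, not a switch).  TRD is an MDD case with at
   least one antidepressant prescription and >= 2 switches.
4. **Adjuncts** — an adherence proxy (proportion of consecutive
   antidepressant prescription intervals <= 98 days, pooling all drugs),
   combination and augmentation flags (>30-day overlap between two
   antidepressants, or between an antidepressant and an antipsychotic /
   mood stabilizer), record-density summaries and cohort-level annual
   prescribing trends.

All interval arithmetic is in whole days with inclusive comparisons
(6 weeks = 42 days, 14 weeks = 98 days).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .ehr_core import (
    EXCLUSION_CATEGORIES,
    PSYCHIATRIC_CATEGORIES,
    ClinicalEvent,
    Codelist,
    DiagnosisCategory,
    DrugClass,
    PrescriptionEvent,
)

#: 14 weeks: maximum gap, in days, between consecutive prescriptions within an
#: episode and between two episodes that form a switch.
MAX_GAP_DAYS = 98
#: 6 weeks: minimum episode span for the episode to qualify for switch logic.
MIN_EPISODE_DAYS = 42
#: Overlap beyond which two concurrent episodes are a combination/augmentation.
COMBINATION_OVERLAP_DAYS = 30
#: Switches required for TRD.
MIN_SWITCHES_FOR_TRD = 2
#: Distinct-date depression codes required for the MDD case definition.
MIN_DEPRESSION_CODES = 2


class MddStatus(str, Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"
    EXCLUDED = "EXCLUDED"


class TrdStatus(str, Enum):
    TRD = "TRD"
    NON_TRD = "NON_TRD"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class ControlScreening(str, Enum):
    """How healthy controls are screened: exclude any psychiatric code
    (primary definition) or only depression codes (sensitivity analysis)."""

    ALL_PSYCHIATRIC = "all_psychiatric"
    MDD_ONLY = "mdd_only"


@dataclass(frozen=True)
class PhenotypingParams:
    """Tunable rule parameters, defaulting to the published definition."""

    min_depression_codes: int = MIN_DEPRESSION_CODES
    gap_days: int = MAX_GAP_DAYS
    min_episode_days: int = MIN_EPISODE_DAYS
    overlap_days: int = COMBINATION_OVERLAP_DAYS
    min_switches: int = MIN_SWITCHES_FOR_TRD
    control_screening: ControlScreening = ControlScreening.ALL_PSYCHIATRIC

    def __post_init__(self) -> None:
        if self.gap_days <= 0 or self.min_episode_days < 0 or self.overlap_days < 0:
            raise ValueError("day parameters must be positive")
        if self.min_depression_codes < 1:
            raise ValueError("min_depression_codes must be >= 1")


@dataclass(frozen=True)
class DrugEpisode:
    """A maximal run of same-drug prescriptions with gaps <= gap_days."""

    patient_id: str
    drug_id: str
    start_date: date
    end_date: date
    n_prescriptions: int

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("episode end_date precedes start_date")

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass(frozen=True)
class SwitchEvent:
    from_episode: DrugEpisode
    to_episode: DrugEpisode

    @property
    def gap_days(self) -> int:
        return (self.to_episode.start_date - self.from_episode.end_date).days


@dataclass
class PhenotypeResult:
    """Per-patient output of the phenotyping algorithm."""

    patient_id: str
    mdd_status: MddStatus
    treated: bool
    trd_status: TrdStatus
    n_switches: int
    adequate_interval_proportion: float | None
    combination_flag: bool
    augmentation_flag: bool
    n_clinical_records: int = 0
    n_prescription_records: int = 0
    n_clinical_dates: int = 0
    n_prescription_dates: int = 0
    records_per_year: float = 0.0
    distinct_dates_per_year: float = 0.0


# -- MDD classification ---------------------------------------------------


def classify_mdd(
    events: Iterable[ClinicalEvent],
    codelist: Codelist,
    min_depression_codes: int = MIN_DEPRESSION_CODES,
    control_screening: ControlScreening = ControlScreening.ALL_PSYCHIATRIC,
) -> MddStatus:
    """Classify one patient's clinical events as CASE / CONTROL / EXCLUDED.

    CASE: >= ``min_depression_codes`` depression codes on distinct dates and
    no bipolar/psychotic/substance-use code.  EXCLUDED covers both an
    exclusion diagnosis and psychiatric coding that falls short of the case
    definition (these patients belong to neither the case nor the control
    set).  CONTROL: no psychiatric code (or, under MDD_ONLY screening, no
    depression code).  An empty record is a CONTROL.
    """
    depression_dates: set[date] = set()
    has_exclusion = False
    has_psychiatric = False
    for ev in events:
        cat = codelist.diagnosis_category(ev.code)
        if cat is DiagnosisCategory.DEPRESSION:
            depression_dates.add(ev.event_date)
        if cat in EXCLUSION_CATEGORIES:
            has_exclusion = True
        if cat in PSYCHIATRIC_CATEGORIES:
            has_psychiatric = True
    if has_exclusion:
        return MddStatus.EXCLUDED
    if len(depression_dates) >= min_depression_codes:
        return MddStatus.CASE
    if control_screening is ControlScreening.ALL_PSYCHIATRIC:
        return MddStatus.EXCLUDED if has_psychiatric else MddStatus.CONTROL
    return MddStatus.EXCLUDED if depression_dates else MddStatus.CONTROL


# -- episode construction and switch detection ----------------------------


def build_drug_episodes(
    prescriptions: Iterable[PrescriptionEvent], gap_days: int = MAX_GAP_DAYS
) -> list[DrugEpisode]:
    """Chain one patient's prescriptions into per-drug episodes.

    Per drug, date-sorted prescriptions with successive gaps <= ``gap_days``
    form one episode; a larger gap starts a new episode.  A single
    prescription yields a zero-duration episode.  Episodes are returned
    sorted chronologically.
    """
    by_drug: dict[str, list[PrescriptionEvent]] = defaultdict(list)
    for rx in prescriptions:
        by_drug[rx.drug_id].append(rx)
    episodes: list[DrugEpisode] = []
    for drug_id, rxs in by_drug.items():
        rxs.sort(key=lambda r: r.issue_date)
        run_start = rxs[0].issue_date
        prev = rxs[0].issue_date
        n = 1
        for rx in rxs[1:]:
            if (rx.issue_date - prev).days <= gap_days:
                n += 1
            else:
                episodes.append(DrugEpisode(rxs[0].patient_id, drug_id, run_start, prev, n))
                run_start = rx.issue_date
                n = 1
            prev = rx.issue_date
        episodes.append(DrugEpisode(rxs[0].patient_id, drug_id, run_start, prev, n))
    episodes.sort(key=lambda e: (e.start_date, e.end_date, e.drug_id))
    return episodes


def episode_overlap_days(a: DrugEpisode, b: DrugEpisode) -> int:
    """Signed overlap of two episodes' date ranges (negative = gap)."""
    return (min(a.end_date, b.end_date) - max(a.start_date, b.start_date)).days


def detect_switches(
    episodes: Sequence[DrugEpisode],
    gap_days: int = MAX_GAP_DAYS,
    min_episode_days: int = MIN_EPISODE_DAYS,
    overlap_days: int = COMBINATION_OVERLAP_DAYS,
) -> list[SwitchEvent]:
    """Detect antidepressant switches in one patient's episode sequence.

    Only qualifying episodes (span >= ``min_episode_days``) are considered,
    in chronological order.  Each adjacent pair with different drugs, a
    between-episode gap of at most ``gap_days``, and a date-range overlap of
    at most ``overlap_days`` (larger overlaps are combinations, analysed
    separately) is a switch.  A->B->A yields two switches: each switch only
    requires the adjacent drugs to differ.
    """
    qualifying = sorted(
        (e for e in episodes if e.duration_days >= min_episode_days),
        key=lambda e: (e.start_date, e.end_date, e.drug_id),
    )
    switches: list[SwitchEvent] = []
    for a, b in zip(qualifying, qualifying[1:]):
        if a.drug_id == b.drug_id:
            continue
        if (b.start_date - a.end_date).days > gap_days:
            continue
        if episode_overlap_days(a, b) > overlap_days:
            continue
        switches.append(SwitchEvent(a, b))
    return switches


def classify_trd(
    mdd_status: MddStatus,
    treated: bool,
    n_switches: int,
    min_switches: int = MIN_SWITCHES_FOR_TRD,
) -> TrdStatus:
    """TRD applies only to treated MDD cases; it requires >= 2 switches."""
    if mdd_status is not MddStatus.CASE or not treated:
        return TrdStatus.NOT_APPLICABLE
    return TrdStatus.TRD if n_switches >= min_switches else TrdStatus.NON_TRD


# -- adherence proxy and co-prescribing flags ------------------------------


def adequate_interval_proportion(
    prescriptions: Iterable[PrescriptionEvent], gap_days: int = MAX_GAP_DAYS
) -> float | None:
    """Proportion of consecutive antidepressant prescription intervals that
    are "adequate" (<= 98 days), pooling all antidepressants.

    This is a compliance proxy, distinct from the switch rules: *every*
    consecutive interval counts, same drug or not.  Returns None with fewer
    than two antidepressant prescriptions (no interval to assess).
    """
    dates = sorted(
        rx.issue_date for rx in prescriptions if rx.drug_class is DrugClass.ANTIDEPRESSANT
    )
    if len(dates) < 2:
        return None
    intervals = [(b - a).days for a, b in zip(dates, dates[1:])]
    return sum(iv <= gap_days for iv in intervals) / len(intervals)


def detect_combination_and_augmentation(
    prescriptions: Iterable[PrescriptionEvent],
    gap_days: int = MAX_GAP_DAYS,
    overlap_days: int = COMBINATION_OVERLAP_DAYS,
) -> tuple[bool, bool]:
    """Flag antidepressant combinations and antipsychotic/mood-stabilizer
    augmentation (episode date ranges overlapping > 30 days)."""
    rxs = list(prescriptions)
    ad_episodes = build_drug_episodes(
        [r for r in rxs if r.drug_class is DrugClass.ANTIDEPRESSANT], gap_days
    )
    adjunct_episodes = build_drug_episodes(
        [
            r
            for r in rxs
            if r.drug_class in (DrugClass.ANTIPSYCHOTIC, DrugClass.MOOD_STABILIZER)
        ],
        gap_days,
    )
    combination = any(
        episode_overlap_days(a, b) > overlap_days
        for i, a in enumerate(ad_episodes)
        for b in ad_episodes[i + 1 :]
        if a.drug_id != b.drug_id
    )
    augmentation = any(
        episode_overlap_days(a, b) > overlap_days
        for a in ad_episodes
        for b in adjunct_episodes
    )
    return combination, augmentation


# -- record density and trends --------------------------------------------


@dataclass(frozen=True)
class RecordDensity:
    n_clinical_records: int
    n_prescription_records: int
    n_clinical_dates: int
    n_prescription_dates: int
    span_years: float
    records_per_year: float
    distinct_dates_per_year: float


def record_density(
    events: Iterable[ClinicalEvent], prescriptions: Iterable[PrescriptionEvent]
) -> RecordDensity:
    """Per-patient record counts, distinct-date counts and per-year rates.

    The observation span is (last record date - first record date)/365.25
    across both tables, floored at 1 year so single-day records still yield a
    finite rate.
    """
    ev_dates = [e.event_date for e in events]
    rx_dates = [r.issue_date for r in prescriptions]
    all_dates = ev_dates + rx_dates
    if not all_dates:
        return RecordDensity(0, 0, 0, 0, 0.0, 0.0, 0.0)
    span_years = max(1.0, (max(all_dates) - min(all_dates)).days / 365.25)
    n_records = len(all_dates)
    n_distinct = len(set(all_dates))
    return RecordDensity(
        n_clinical_records=len(ev_dates),
        n_prescription_records=len(rx_dates),
        n_clinical_dates=len(set(ev_dates)),
        n_prescription_dates=len(set(rx_dates)),
        span_years=span_years,
        records_per_year=n_records / span_years,
        distinct_dates_per_year=n_distinct / span_years,
    )


def annual_trends(prescriptions: Iterable[PrescriptionEvent]) -> pd.DataFrame:
    """Cohort-level calendar-year prescription counts per drug and class.

    Returns a tidy frame with columns ``year, drug_id, drug_class, n``; class
    totals are by construction the sum over member drugs.
    """
    rows = [
        (rx.issue_date.year, rx.drug_id, rx.drug_class.value) for rx in prescriptions
    ]
    if not rows:
        return pd.DataFrame(columns=["year", "drug_id", "drug_class", "n"])
    df = pd.DataFrame(rows, columns=["year", "drug_id", "drug_class"])
    out = (
        df.groupby(["year", "drug_id", "drug_class"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
        .sort_values(["year", "drug_id"], ignore_index=True)
    )
    return out


# -- per-patient and cohort drivers ----------------------------------------


def phenotype_patient(
    patient_id: str,
    events: Sequence[ClinicalEvent],
    prescriptions: Sequence[PrescriptionEvent],
    codelist: Codelist,
    params: PhenotypingParams = PhenotypingParams(),
) -> PhenotypeResult:
    """Run the full per-patient algorithm and assemble a PhenotypeResult."""
    mdd = classify_mdd(
        events, codelist, params.min_depression_codes, params.control_screening
    )
    ad_rxs = [r for r in prescriptions if r.drug_class is DrugClass.ANTIDEPRESSANT]
    treated = len(ad_rxs) > 0
    episodes = build_drug_episodes(ad_rxs, params.gap_days)
    switches = detect_switches(
        episodes, params.gap_days, params.min_episode_days, params.overlap_days
    )
    trd = classify_trd(mdd, treated, len(switches), params.min_switches)
    combination, augmentation = detect_combination_and_augmentation(
        prescriptions, params.gap_days, params.overlap_days
    )
    density = record_density(events, prescriptions)
    return PhenotypeResult(
        patient_id=patient_id,
        mdd_status=mdd,
        treated=treated,
        trd_status=trd,
        n_switches=len(switches),
        adequate_interval_proportion=adequate_interval_proportion(ad_rxs, params.gap_days),
        combination_flag=combination,
        augmentation_flag=augmentation,
        n_clinical_records=density.n_clinical_records,
        n_prescription_records=density.n_prescription_records,
        n_clinical_dates=density.n_clinical_dates,
        n_prescription_dates=density.n_prescription_dates,
        records_per_year=density.records_per_year,
        distinct_dates_per_year=density.distinct_dates_per_year,
    )


def phenotype_cohort(
    events: Iterable[ClinicalEvent],
    prescriptions: Iterable[PrescriptionEvent],
    codelist: Codelist,
    params: PhenotypingParams = PhenotypingParams(),
) -> pd.DataFrame:
    """Phenotype every patient appearing in either table.

    Output is one row per patient with the PhenotypeResult fields; the result
    is invariant to the order of input rows.
    """
    ev_by_pat: dict[str, list[ClinicalEvent]] = defaultdict(list)
    rx_by_pat: dict[str, list[PrescriptionEvent]] = defaultdict(list)
    for e in events:
        ev_by_pat[e.patient_id].append(e)
    for r in prescriptions:
        rx_by_pat[r.patient_id].append(r)
    patient_ids = sorted(set(ev_by_pat) | set(rx_by_pat))
    rows = []
    for pid in patient_ids:
        res = phenotype_patient(
            pid, ev_by_pat.get(pid, []), rx_by_pat.get(pid, []), codelist, params
        )
        rows.append(
            {
                "patient_id": res.patient_id,
                "mdd_status": res.mdd_status.value,
                "treated": res.treated,
                "trd_status": res.trd_status.value,
                "n_switches": res.n_switches,
                "adequate_interval_proportion": res.adequate_interval_proportion,
                "combination_flag": res.combination_flag,
                "augmentation_flag": res.augmentation_flag,
                "n_clinical_records": res.n_clinical_records,
                "n_prescription_records": res.n_prescription_records,
                "n_clinical_dates": res.n_clinical_dates,
                "n_prescription_dates": res.n_prescription_dates,
                "records_per_year": res.records_per_year,
                "distinct_dates_per_year": res.distinct_dates_per_year,
            }
        )
    columns = [
        "patient_id", "mdd_status", "treated", "trd_status", "n_switches",
        "adequate_interval_proportion", "combination_flag", "augmentation_flag",
        "n_clinical_records", "n_prescription_records", "n_clinical_dates",
        "n_prescription_dates", "records_per_year", "distinct_dates_per_year",
    ]
    return pd.DataFrame(rows, columns=columns)
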