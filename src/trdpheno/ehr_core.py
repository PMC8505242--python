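"""Domain types, codelists and table I/O for primary-care style EHR extracts.

The raw inputs are two delimited tables mirroring UK primary-care extracts
(``gp_clinical`` / ``gp_scripts``): a clinical-events table with columns
``patient_id,event_dt,read_2,read_3`` and a prescriptions table with columns
``patient_id,issue_date,drug_name,raw_code``.  Codelists map clinical codes to
diagnostic categories and drug-name patterns to canonical substances with a
pharmacological class.  Everything downstream (phenotyping, simulation,
statistics) consumes the typed records defined here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("trdpheno")

CLINICAL_COLUMNS = ["patient_id", "event_dt", "read_2", "read_3"]
PRESCRIPTION_COLUMNS = ["patient_id", "issue_date", "drug_name", "raw_code"]


class CodeSystem(str, Enum):
    READ2 = "READ2"
    CTV3 = "CTV3"


class DiagnosisCategory(str, Enum):
    DEPRESSION = "DEPRESSION"
    BIPOLAR = "BIPOLAR"
    PSYCHOTIC = "PSYCHOTIC"
    SUBSTANCE_USE = "SUBSTANCE_USE"
    OTHER_PSYCHIATRIC = "OTHER_PSYCHIATRIC"
    NON_PSYCHIATRIC = "NON_PSYCHIATRIC"


#: Diagnoses that exclude a patient from the MDD case definition
#: (bipolar depression, psychotic disorders, substance-use disorders).
EXCLUSION_CATEGORIES = frozenset(
    {DiagnosisCategory.BIPOLAR, DiagnosisCategory.PSYCHOTIC, DiagnosisCategory.SUBSTANCE_USE}
)

#: Any psychiatric diagnosis (used to screen healthy controls).
PSYCHIATRIC_CATEGORIES = frozenset(
    {
        DiagnosisCategory.DEPRESSION,
        DiagnosisCategory.BIPOLAR,
        DiagnosisCategory.PSYCHOTIC,
        DiagnosisCategory.SUBSTANCE_USE,
        DiagnosisCategory.OTHER_PSYCHIATRIC,
    }
)


class DrugClass(str, Enum):
    ANTIDEPRESSANT = "ANTIDEPRESSANT"
    ANTIPSYCHOTIC = "ANTIPSYCHOTIC"
    MOOD_STABILIZER = "MOOD_STABILIZER"
    OTHER = "OTHER"


@dataclass(frozen=True, order=True)
class ClinicalEvent:
    """A dated, coded clinical record for one patient."""

    patient_id: str
    event_date: date
    code: str
    code_system: CodeSystem

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("clinical code must be non-empty")


@dataclass(frozen=True, order=True)
class PrescriptionEvent:
    """A dated drug issue for one patient.

    ``drug_id`` is the canonical substance name and ``drug_class`` is always
    assigned from the drug codelist, never inferred ad hoc.
    """

    patient_id: str
    issue_date: date
    drug_id: str
    drug_class: DrugClass
    raw_code: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


@dataclass
class Codelist:
    """Total lookups from clinical codes to diagnostic categories and from
    drug-name patterns to ``(drug_id, drug_class)``.

    Unknown clinical codes map to ``NON_PSYCHIATRIC`` and unknown drug names
    to class ``OTHER`` so that exclusion logic stays conservative; both
    fallbacks increment warning counters instead of dropping rows.
    """

    diagnosis_map: dict[str, DiagnosisCategory] = field(default_factory=dict)
    drug_map: dict[str, tuple[str, DrugClass]] = field(default_factory=dict)
    unknown_diagnosis_codes: Counter = field(default_factory=Counter)
    unknown_drug_names: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.drug_map = {k.lower(): v for k, v in self.drug_map.items()}

    def diagnosis_category(self, code: str) -> DiagnosisCategory:
        try:
            return self.diagnosis_map[code]
        except KeyError:
            self.unknown_diagnosis_codes[code] += 1
            return DiagnosisCategory.NON_PSYCHIATRIC

    def drug_lookup(self, drug_name: str) -> tuple[str, DrugClass]:
        """Canonicalise a (possibly product-level) drug name.

        Matching is case-insensitive longest-prefix against the pattern keys,
        so "Citalopram 20mg tablets" resolves to substance "citalopram".
        Unmapped products keep their lower-cased name with class OTHER.
        """
        name = drug_name.strip().lower()
        best: str | None = None
        for pattern in self.drug_map:
            if name.startswith(pattern) and (best is None or len(pattern) > len(best)):
                best = pattern
        if best is not None:
            return self.drug_map[best]
        self.unknown_drug_names[drug_name] += 1
        return name, DrugClass.OTHER

    # -- file loading -----------------------------------------------------

    @classmethod
    def from_files(cls, diagnosis_path: str | Path, drug_path: str | Path) -> "Codelist":
        """Load the two-column (code, category) and three-column
        (pattern, drug_id, class) delimited codelist files."""
        dx = _read_delimited(diagnosis_path)
        rx = _read_delimited(drug_path)
        diagnosis_map = {
            str(row.iloc[0]).strip(): DiagnosisCategory(str(row.iloc[1]).strip().upper())
            for _, row in dx.iterrows()
        }
        drug_map = {
            str(row.iloc[0]).strip().lower(): (
                str(row.iloc[1]).strip().lower(),
                DrugClass(str(row.iloc[2]).strip().upper()),
            )
            for _, row in rx.iterrows()
        }
        return cls(diagnosis_map=diagnosis_map, drug_map=drug_map)

    def to_files(self, diagnosis_path: str | Path, drug_path: str | Path) -> None:
        pd.DataFrame(
            [(c, cat.value) for c, cat in self.diagnosis_map.items()],
            columns=["code", "category"],
        ).to_csv(diagnosis_path, index=False)
        pd.DataFrame(
            [(p, d, k.value) for p, (d, k) in self.drug_map.items()],
            columns=["pattern", "drug_id", "class"],
        ).to_csv(drug_path, index=False)


# Illustrative codelist: code vocabularies in real extracts are user input;
# these entries only need to be internally consistent for simulation/testing.
_EXAMPLE_DIAGNOSIS_CODES = {
    "E112.": DiagnosisCategory.DEPRESSION,   # Read v2 style
    "E113.": DiagnosisCategory.DEPRESSION,
    "E2B0.": DiagnosisCategory.DEPRESSION,
    "X00SL": DiagnosisCategory.DEPRESSION,   # CTV3 style
    "E110.": DiagnosisCategory.BIPOLAR,
    "E10..": DiagnosisCategory.PSYCHOTIC,
    "E23..": DiagnosisCategory.SUBSTANCE_USE,
    "E200.": DiagnosisCategory.OTHER_PSYCHIATRIC,
    "H33..": DiagnosisCategory.NON_PSYCHIATRIC,
    "G20..": DiagnosisCategory.NON_PSYCHIATRIC,
}

_EXAMPLE_ANTIDEPRESSANTS = [
    "citalopram", "sertraline", "fluoxetine", "paroxetine", "escitalopram",
    "venlafaxine", "duloxetine", "mirtazapine", "amitriptyline", "trazodone",
]
_EXAMPLE_ANTIPSYCHOTICS = ["quetiapine", "olanzapine", "risperidone", "aripiprazole"]
_EXAMPLE_MOOD_STABILIZERS = ["lithium", "lamotrigine", "valproate"]


def example_codelist() -> Codelist:
    """Illustrative codelist used by the synthetic generator and the docs.

    Real depression/exclusion codelists are study-specific and supplied by the
    user; this one exists so the whole pipeline runs with no external data.
    """
    drug_map: dict[str, tuple[str, DrugClass]] = {}
    for name in _EXAMPLE_ANTIDEPRESSANTS:
        drug_map[name] = (name, DrugClass.ANTIDEPRESSANT)
    for name in _EXAMPLE_ANTIPSYCHOTICS:
        drug_map[name] = (name, DrugClass.ANTIPSYCHOTIC)
    for name in _EXAMPLE_MOOD_STABILIZERS:
        drug_map[name] = (name, DrugClass.MOOD_STABILIZER)
    drug_map["paracetamol"] = ("paracetamol", DrugClass.OTHER)
    return Codelist(diagnosis_map=dict(_EXAMPLE_DIAGNOSIS_CODES), drug_map=drug_map)


# -- table readers/writers ------------------------------------------------


@dataclass
class ReadResult:
    """Parsed events plus row-level parse accounting (nothing is silently
    dropped: rejected rows are counted and logged)."""

    events: list
    n_rows: int = 0
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; everything is read as raw strings
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _parse_date(text: str) -> date | None:
    try:
        return date.fromisoformat(text.strip())
    except ValueError:
        return None


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")


def read_clinical_table(path: str | Path, codelist: Codelist) -> ReadResult:
    """Read a ``patient_id,event_dt,read_2,read_3`` table into ClinicalEvents.

    When a row carries both a Read v2 and a CTV3 code the Read v2 code is
    used, giving each row a single deterministic category assignment.  Rows
    with an unparseable date or no code are rejected and counted.
    """
    df = _read_delimited(path)
    _require_columns(df, ["patient_id", "event_dt"], path)
    if "read_2" not in df.columns and "read_3" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'read_2' (or 'read_3')")
    events: list[ClinicalEvent] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        d = _parse_date(getattr(row, "event_dt"))
        read2 = getattr(row, "read_2", "").strip() if hasattr(row, "read_2") else ""
        read3 = getattr(row, "read_3", "").strip() if hasattr(row, "read_3") else ""
        if d is None or not (read2 or read3):
            n_rejected += 1
            continue
        code, system = (read2, CodeSystem.READ2) if read2 else (read3, CodeSystem.CTV3)
        events.append(ClinicalEvent(str(getattr(row, "patient_id")), d, code, system))
    if n_rejected:
        logger.warning("%s: rejected %d of %d clinical rows", path, n_rejected, len(df))
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.code))
    return ReadResult(events, n_rows=len(df), n_rejected=n_rejected)


def read_prescription_table(path: str | Path, codelist: Codelist) -> ReadResult:
    """Read a ``patient_id,issue_date,drug_name,raw_code`` table into
    PrescriptionEvents, canonicalising drug names through the codelist."""
    df = _read_delimited(path)
    _require_columns(df, ["patient_id", "issue_date", "drug_name"], path)
    events: list[PrescriptionEvent] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        d = _parse_date(getattr(row, "issue_date"))
        name = getattr(row, "drug_name", "").strip()
        if d is None or not name:
            n_rejected += 1
            continue
        drug_id, drug_class = codelist.drug_lookup(name)
        raw = getattr(row, "raw_code", "") if hasattr(row, "raw_code") else ""
        events.append(
            PrescriptionEvent(
                str(getattr(row, "patient_id")), d, drug_id, drug_class, raw or None
            )
        )
    if n_rejected:
        logger.warning("%s: rejected %d of %d prescription rows", path, n_rejected, len(df))
    events.sort(key=lambda e: (e.patient_id, e.issue_date, e.drug_id))
    return ReadResult(events, n_rows=len(df), n_rejected=n_rejected)


def write_clinical_table(events: Iterable[ClinicalEvent], path: str | Path, sep: str = ",") -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "event_dt": e.event_date.isoformat(),
            "read_2": e.code if e.code_system is CodeSystem.READ2 else "",
            "read_3": e.code if e.code_system is CodeSystem.CTV3 else "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep=sep, index=False)


def write_prescription_table(
    events: Iterable[PrescriptionEvent], path: str | Path, sep: str = ","
) -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "issue_date": e.issue_date.isoformat(),
            "drug_name": e.drug_id,
            "raw_code": e.raw_code or "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS).to_csv(path, sep=sep, index=False)
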