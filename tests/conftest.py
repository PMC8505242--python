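from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from trdpheno import (
    ClinicalEvent,
    CodeSystem,
    DrugClass,
    PrescriptionEvent,
    example_codelist,
)


@pytest.fixture
def codelist():
    return example_codelist()


def rx(day: int, drug: str = "citalopram", drug_class=DrugClass.ANTIDEPRESSANT,
       pid: str = "P1", origin: date = date(2005, 1, 1)) -> PrescriptionEvent:
    """Prescription on day offset ``day`` from a fixed origin."""
    return PrescriptionEvent(pid, origin + timedelta(days=day), drug, drug_class)


def dx(day: int, code: str = "E112.", pid: str = "P1",
       origin: date = date(2005, 1, 1)) -> ClinicalEvent:
    return ClinicalEvent(pid, origin + timedelta(days=day), code, CodeSystem.READ2)


def episode_rx(start_day: int, drug: str, span: int = 56, step: int = 28,
               **kwargs) -> list[PrescriptionEvent]:
    """Prescriptions every ``step`` days from start_day until span is covered."""
    days = list(range(start_day, start_day + span + 1, step))
    if days[-1] != start_day + span:
        days.append(start_day + span)
    return [rx(d, drug, **kwargs) for d in days]
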