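from __future__ import annotations

from datetime import date

import pytest

from neuroclaims.codebook import Codebook
from neuroclaims.records import (
    DischargeRecord,
    EventHistory,
    ExemptionRecord,
    PersonRecord,
    PrescriptionRecord,
)


def make_person(
    pid: str = "p1",
    sex: str = "female",
    birth: date = date(1950, 6, 15),
    death: date | None = None,
    muni: str = "M001",
    residency_start: date | None = date(2016, 1, 1),
    residency_end: date | None = None,
) -> PersonRecord:
    return PersonRecord(
        person_id=pid,
        sex=sex,
        birth_date=birth,
        death_date=death,
        municipality_id=muni,
        residency_start=residency_start,
        residency_end=residency_end if residency_end is not None else death,
    )


def make_history(
    person: PersonRecord | None = None,
    rx: list[tuple[date, str]] = (),
    hdr: list[tuple[date, list[str]]] = (),
    ex: list[tuple[date, str]] = (),
) -> EventHistory:
    person = person or make_person()
    h = EventHistory(
        person=person,
        prescriptions=[
            PrescriptionRecord(person.person_id, d, atc) for d, atc in rx
        ],
        discharges=[
            DischargeRecord(person.person_id, d, d, tuple(dxs)) for d, dxs in hdr
        ],
        exemptions=[ExemptionRecord(person.person_id, code, d) for d, code in ex],
    )
    h.sort()
    return h


@pytest.fixture
def codebook() -> Codebook:
    return Codebook()


@pytest.fixture
def person() -> PersonRecord:
    return make_person()
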