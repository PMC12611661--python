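"""Case adjudication from per-person event histories.

A person qualifies as a parkinsonism case through repeated
antiparkinsonian prescriptions or a disease-specific exemption, and as
a dementia case through any of: repeated anti-dementia prescriptions, a
dementia diagnosis on a hospital discharge, a dementia exemption, or
repeated proxy-drug use (antipsychotics / trazodone / mirtazapine).
Proxy-only cases are vetoed when any psychiatric diagnosis or exemption
appears anywhere in the person's history.

Incident status requires a disease-free look-back across all three
event sources (any matching prescription, diagnosis or exemption counts
as evidence, repeated or not), truncated at the start of the available
study window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

from neuroclaims.codebook import Codebook
from neuroclaims.records import EventHistory, PrescriptionRecord

__all__ = [
    "CaseRecord",
    "Classification",
    "IdentificationResult",
    "qualifies_repeated",
    "classify_parkinsonism",
    "classify_dementia",
    "assign_group",
    "is_incident",
    "identify_cohort",
    "incident_counts_by_year",
]

GROUPS = ("parkinsonism", "dementia", "both")

# ATC subgroup labels for the drug-attribution breakdown
_DRUG_SUBGROUPS = (
    ("N06AX05", "trazodone"),
    ("N06AX11", "mirtazapine"),
    ("N06DX01", "memantine"),
    ("N04BA", "N04BA"),
    ("N04BC", "N04BC"),
    ("N06DA", "N06DA"),
    ("N05A", "N05A"),
    ("N04", "other_antiparkinsonian"),
)


def _drug_subgroup(atc: str) -> str:
    for prefix, label in _DRUG_SUBGROUPS:
        if atc.startswith(prefix):
            return label
    return "other"


@dataclass(frozen=True)
class Classification:
    is_case: bool
    criteria: frozenset[str]
    sources: frozenset[str]
    first_date: date | None
    excluded_psychiatric: bool = False


@dataclass(frozen=True)
class CaseRecord:
    person_id: str
    group: str
    sources: frozenset[str]
    criteria_met: frozenset[str]
    first_evidence_date: date
    incident: bool
    excluded_psychiatric: bool = False
    died_in_reference_year: bool = False


@dataclass
class IdentificationResult:
    cases: list[CaseRecord]
    excluded_psychiatric_count: int
    source_breakdown: dict[str, dict[str, int]]
    drug_breakdown: dict[str, dict[str, int]]

    def by_group(self) -> dict[str, list[CaseRecord]]:
        out: dict[str, list[CaseRecord]] = {g: [] for g in GROUPS}
        for c in self.cases:
            out[c.group].append(c)
        return out


def qualifies_repeated(
    prescriptions: Sequence[PrescriptionRecord],
    atc_set: frozenset[str],
    codebook: Codebook,
) -> tuple[bool, date | None]:
    """Test the 'repeated prescriptions' rule for one ATC prefix set.

    True iff at least ``repeat_min_count`` matching prescriptions fall
    within some span of ``repeat_window_days`` (closed); returns the
    first prescription date of the earliest qualifying span.
    """
    dates = sorted(
        r.dispense_date for r in prescriptions if codebook.matches_atc(r.atc_code, atc_set)
    )
    m = codebook.repeat_min_count
    for i in range(len(dates) - m + 1):
        if (dates[i + m - 1] - dates[i]).days <= codebook.repeat_window_days:
            return True, dates[i]
    return False, None


def _events_until(history: EventHistory, as_of: date) -> EventHistory:
    return EventHistory(
        person=history.person,
        prescriptions=[r for r in history.prescriptions if r.dispense_date <= as_of],
        discharges=[r for r in history.discharges if r.admission_date <= as_of],
        exemptions=[r for r in history.exemptions if r.start_date <= as_of],
    )


def classify_parkinsonism(
    history: EventHistory, codebook: Codebook, as_of: date
) -> Classification:
    h = _events_until(history, as_of)
    criteria: set[str] = set()
    sources: set[str] = set()
    dates: list[date] = []

    ok, first = qualifies_repeated(h.prescriptions, codebook.park_atc, codebook)
    if ok:
        criteria.add("park_rx")
        sources.add("prescription")
        dates.append(first)
    ex_dates = [r.start_date for r in h.exemptions if r.exemption_code in codebook.park_exemption]
    if ex_dates:
        criteria.add("park_exemption")
        sources.add("exemption")
        dates.append(min(ex_dates))

    return Classification(
        is_case=bool(criteria),
        criteria=frozenset(criteria),
        sources=frozenset(sources),
        first_date=min(dates) if dates else None,
    )


def classify_dementia(history: EventHistory, codebook: Codebook, as_of: date) -> Classification:
    h = _events_until(history, as_of)
    criteria: set[str] = set()
    sources: set[str] = set()
    dates: list[date] = []

    ok, first = qualifies_repeated(h.prescriptions, codebook.dementia_atc, codebook)
    if ok:
        criteria.add("dem_rx")
        sources.add("prescription")
        dates.append(first)

    hdr_dates = [
        r.admission_date
        for r in h.discharges
        if any(codebook.matches_dementia_icd9(dx) for dx in r.diagnoses)
    ]
    if hdr_dates:
        criteria.add("dem_hdr")
        sources.add("discharge")
        dates.append(min(hdr_dates))

    ex_dates = [
        r.start_date for r in h.exemptions if r.exemption_code in codebook.dementia_exemption
    ]
    if ex_dates:
        criteria.add("dem_exemption")
        sources.add("exemption")
        dates.append(min(ex_dates))

    ok, first = qualifies_repeated(h.prescriptions, codebook.proxy_atc, codebook)
    if ok:
        criteria.add("dem_proxy")
        sources.add("prescription")
        dates.append(first)

    if criteria == {"dem_proxy"} and _has_psychiatric_label(history, codebook):
        # proxy evidence alone is not trusted for psychiatric patients;
        # the veto scans the entire history, not only the window up to as_of
        return Classification(
            is_case=False,
            criteria=frozenset(),
            sources=frozenset(),
            first_date=None,
            excluded_psychiatric=True,
        )

    return Classification(
        is_case=bool(criteria),
        criteria=frozenset(criteria),
        sources=frozenset(sources),
        first_date=min(dates) if dates else None,
    )


def _has_psychiatric_label(history: EventHistory, codebook: Codebook) -> bool:
    if any(r.exemption_code in codebook.psych_exemption for r in history.exemptions):
        return True
    return any(
        codebook.matches_psych_icd9(dx) for r in history.discharges for dx in r.diagnoses
    )


def assign_group(park: bool, dem: bool) -> str | None:
    if park and dem:
        return "both"
    if park:
        return "parkinsonism"
    if dem:
        return "dementia"
    return None


def _evidence_years(history: EventHistory, codebook: Codebook) -> set[int]:
    """Calendar years holding any disease evidence in any source.

    A single matching prescription counts here even though case status
    itself demands repetition: the look-back excludes anyone with *any*
    prior trace of the disease, proxy drugs included.
    """
    tracer_atc = codebook.park_atc | codebook.dementia_atc | codebook.proxy_atc
    years = {
        r.dispense_date.year
        for r in history.prescriptions
        if codebook.matches_atc(r.atc_code, tracer_atc)
    }
    years |= {
        r.admission_date.year
        for r in history.discharges
        if any(codebook.matches_dementia_icd9(dx) for dx in r.diagnoses)
    }
    tracer_ex = codebook.park_exemption | codebook.dementia_exemption
    years |= {r.start_date.year for r in history.exemptions if r.exemption_code in tracer_ex}
    return years


def is_incident(
    history: EventHistory,
    codebook: Codebook,
    year: int,
    lookback_years: int = 5,
    study_start_year: int | None = None,
) -> bool:
    """Disease-free look-back: no evidence in the ``lookback_years``
    calendar years before ``year``, truncated at the study start."""
    years = _evidence_years(history, codebook)
    if years and min(years) > year:
        raise ValueError(f"first evidence after year {year}; contract violated")
    lo = year - lookback_years
    if study_start_year is not None:
        lo = max(lo, study_start_year)
    return not any(lo <= y <= year - 1 for y in years)


def _first_qualifying_drug(
    history: EventHistory, codebook: Codebook, as_of: date, group: str
) -> str | None:
    """ATC subgroup of the earliest prescription that belongs to a met
    drug criterion; None for cases identified without drugs."""
    if group == "parkinsonism":
        sets = [codebook.park_atc]
    elif group == "dementia":
        sets = [codebook.dementia_atc, codebook.proxy_atc]
    else:
        sets = [codebook.park_atc, codebook.dementia_atc, codebook.proxy_atc]
    best: tuple[date, str] | None = None
    for atc_set in sets:
        ok, first = qualifies_repeated(
            [r for r in history.prescriptions if r.dispense_date <= as_of], atc_set, codebook
        )
        if not ok:
            continue
        for r in history.prescriptions:
            if r.dispense_date == first and codebook.matches_atc(r.atc_code, atc_set):
                if best is None or first < best[0]:
                    best = (first, _drug_subgroup(r.atc_code))
                break
    return best[1] if best else None


def identify_cohort(
    histories: Mapping[str, EventHistory] | Iterable[EventHistory],
    codebook: Codebook,
    reference_year: int,
    lookback_years: int = 5,
    study_start_year: int | None = None,
) -> IdentificationResult:
    """Adjudicate every person against the reference year.

    Emits one :class:`CaseRecord` per person who meets parkinsonism
    and/or dementia criteria by Dec 31 of the reference year, is
    resident then, and did not die before the reference year.  The
    result also tallies proxy-only persons vetoed for psychiatric
    labels, per-source contributions per group, and the ATC-subgroup
    attribution of drug-identified cases.
    """
    if not isinstance(histories, Mapping):
        histories = {h.person.person_id: h for h in histories}
    ref_end = date(reference_year, 12, 31)

    cases: list[CaseRecord] = []
    excluded = 0
    src: dict[str, dict[str, int]] = {
        g: {"prescription": 0, "discharge": 0, "exemption": 0} for g in GROUPS
    }
    drugs: dict[str, dict[str, int]] = {g: {} for g in GROUPS}

    for pid in sorted(histories):
        h = histories[pid]
        p = h.person
        if not p.resident_on(ref_end) and not (
            p.death_date is not None
            and p.death_date.year == reference_year
            and p.resident_on(p.death_date)
        ):
            continue
        if p.death_date is not None and p.death_date.year < reference_year:
            continue
        park = classify_parkinsonism(h, codebook, ref_end)
        dem = classify_dementia(h, codebook, ref_end)
        if dem.excluded_psychiatric:
            excluded += 1
        group = assign_group(park.is_case, dem.is_case)
        if group is None:
            continue
        first = min(d for d in (park.first_date, dem.first_date) if d is not None)
        incident = first.year == reference_year and is_incident(
            h, codebook, reference_year, lookback_years, study_start_year
        )
        rec = CaseRecord(
            person_id=pid,
            group=group,
            sources=park.sources | dem.sources,
            criteria_met=park.criteria | dem.criteria,
            first_evidence_date=first,
            incident=incident,
            died_in_reference_year=(
                p.death_date is not None and p.death_date.year == reference_year
            ),
        )
        cases.append(rec)
        for s in rec.sources:
            src[group][s] += 1
        sub = _first_qualifying_drug(h, codebook, ref_end, group)
        if sub is not None:
            drugs[group][sub] = drugs[group].get(sub, 0) + 1

    return IdentificationResult(
        cases=cases,
        excluded_psychiatric_count=excluded,
        source_breakdown=src,
        drug_breakdown=drugs,
    )


def incident_counts_by_year(
    histories: Mapping[str, EventHistory],
    codebook: Codebook,
    years: Sequence[int],
    lookback_years: int = 5,
    study_start_year: int | None = None,
) -> dict[int, dict[str, int]]:
    """Per-year incident case counts by group (first evidence in that
    year with a clean, possibly truncated, look-back)."""
    out: dict[int, dict[str, int]] = {y: {g: 0 for g in GROUPS} for y in years}
    for pid in sorted(histories):
        h = histories[pid]
        ev_years = _evidence_years(h, codebook)
        if not ev_years:
            continue
        y0 = min(ev_years)
        if y0 not in out:
            continue
        if not is_incident(h, codebook, y0, lookback_years, study_start_year):
            continue
        as_of = date(y0, 12, 31)
        park = classify_parkinsonism(h, codebook, as_of)
        dem = classify_dementia(h, codebook, as_of)
        group = assign_group(park.is_case, dem.is_case)
        if group is not None:
            out[y0][group] += 1
    return out
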