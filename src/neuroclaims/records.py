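"""Record schemas, file I/O, pseudonymization and per-person linkage.

The four administrative sources are flat tables keyed by an opaque
``person_id``.  Readers are deliberately forgiving at the row level
(dirty rows are rejected and counted, not fatal) but strict about
schema: a missing column is an error.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PersonRecord",
    "PrescriptionRecord",
    "DischargeRecord",
    "ExemptionRecord",
    "EventHistory",
    "LoadReport",
    "SchemaError",
    "pseudonymize",
    "read_source",
    "write_source",
    "build_histories",
]

SOURCE_KINDS = ("registry", "prescriptions", "discharges", "exemptions")

_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "registry": (
        "person_id",
        "sex",
        "birth_date",
        "death_date",
        "municipality_id",
        "residency_start",
        "residency_end",
    ),
    "prescriptions": ("person_id", "dispense_date", "atc_code"),
    "discharges": (
        "person_id",
        "admission_date",
        "discharge_date",
        "dx1",
        "dx2",
        "dx3",
        "dx4",
        "dx5",
        "dx6",
    ),
    "exemptions": ("person_id", "exemption_code", "start_date"),
}

SEX_VALUES = ("male", "female")


class SchemaError(ValueError):
    """Raised when an input file does not carry the documented columns."""


@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    sex: str
    birth_date: date
    death_date: date | None
    municipality_id: str
    residency_start: date | None = None
    residency_end: date | None = None

    def alive_on(self, day: date) -> bool:
        # closed intervals: a person who dies on `day` is counted alive then
        return self.death_date is None or self.death_date >= day

    def resident_on(self, day: date) -> bool:
        if self.residency_start is not None and self.residency_start > day:
            return False
        return self.residency_end is None or self.residency_end >= day

    def age_on(self, day: date) -> int:
        born = self.birth_date
        return day.year - born.year - ((day.month, day.day) < (born.month, born.day))


@dataclass(frozen=True)
class PrescriptionRecord:
    person_id: str
    dispense_date: date
    atc_code: str


@dataclass(frozen=True)
class DischargeRecord:
    person_id: str
    admission_date: date
    discharge_date: date
    diagnoses: tuple[str, ...]


@dataclass(frozen=True)
class ExemptionRecord:
    person_id: str
    exemption_code: str
    start_date: date


@dataclass
class EventHistory:
    """All events of one person, each stream sorted ascending by date."""

    person: PersonRecord
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    discharges: list[DischargeRecord] = field(default_factory=list)
    exemptions: list[ExemptionRecord] = field(default_factory=list)

    def sort(self) -> None:
        self.prescriptions.sort(key=lambda r: r.dispense_date)
        self.discharges.sort(key=lambda r: r.admission_date)
        self.exemptions.sort(key=lambda r: r.start_date)

    @property
    def n_events(self) -> int:
        return len(self.prescriptions) + len(self.discharges) + len(self.exemptions)


@dataclass
class LoadReport:
    path: str
    source_kind: str
    n_rows: int = 0
    n_loaded: int = 0
    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)

    def reject(self, row_index: int, why: str, max_logged: int = 50) -> None:
        self.n_rejected += 1
        if len(self.reasons) < max_logged:
            self.reasons.append(f"row {row_index}: {why}")


def pseudonymize(raw_id: str, secret_key: bytes) -> str:
    """Map a raw identifier to a stable, irreversible 16-hex-char pseudo-ID.

    Keyed HMAC-SHA256 digest truncated to 64 bits: deterministic for a
    fixed key, one-way, and with negligible collision probability at
    registry scale (~1.5 M persons).
    """
    if not raw_id:
        raise ValueError("raw_id must be non-empty")
    if not isinstance(secret_key, (bytes, bytearray)):
        raise TypeError("secret_key must be bytes")
    return hmac.new(bytes(secret_key), raw_id.encode("utf-8"), hashlib.sha256).hexdigest()[:16]


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, date):
        return value
    s = str(value).strip()
    if not s or s.lower() in ("nan", "nat", "none"):
        return None
    ts = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    if pd.isna(ts):
        raise ValueError(f"unparseable date {value!r}")
    return ts.date()


def _read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for {kind}")
    return df


def read_source(path: str | Path, source_kind: str) -> tuple[list, LoadReport]:
    """Load one source file into typed records.

    Rows violating per-record invariants are rejected and counted in the
    returned :class:`LoadReport`; schema problems raise :class:`SchemaError`.
    """
    if source_kind not in SOURCE_KINDS:
        raise ValueError(f"unknown source_kind {source_kind!r}")
    df = _read_table(path, source_kind)
    report = LoadReport(path=str(path), source_kind=source_kind, n_rows=len(df))
    parser = {
        "registry": _parse_registry_row,
        "prescriptions": _parse_prescription_row,
        "discharges": _parse_discharge_row,
        "exemptions": _parse_exemption_row,
    }[source_kind]
    out: list = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(parser(row))
        except ValueError as exc:
            report.reject(i, str(exc))
    report.n_loaded = len(out)
    return out, report


def _nonempty(value, name: str) -> str:
    s = "" if value is None else str(value).strip()
    if not s or s.lower() in ("nan", "none"):
        raise ValueError(f"{name} is empty")
    return s


def _parse_registry_row(row) -> PersonRecord:
    sex = _nonempty(row.sex, "sex").lower()
    if sex not in SEX_VALUES:
        raise ValueError(f"invalid sex {row.sex!r}")
    birth = _parse_date(row.birth_date)
    if birth is None:
        raise ValueError("birth_date missing")
    death = _parse_date(row.death_date)
    if death is not None and not birth < death:
        raise ValueError("birth_date must precede death_date")
    res_start = _parse_date(row.residency_start)
    res_end = _parse_date(row.residency_end)
    if res_start is not None and res_end is not None and res_start > res_end:
        raise ValueError("residency interval ill-ordered")
    return PersonRecord(
        person_id=_nonempty(row.person_id, "person_id"),
        sex=sex,
        birth_date=birth,
        death_date=death,
        municipality_id=_nonempty(row.municipality_id, "municipality_id"),
        residency_start=res_start,
        residency_end=res_end,
    )


def _parse_prescription_row(row) -> PrescriptionRecord:
    atc = _nonempty(row.atc_code, "atc_code").upper()
    if not atc.isalnum():
        raise ValueError(f"atc_code {atc!r} not alphanumeric")
    d = _parse_date(row.dispense_date)
    if d is None:
        raise ValueError("dispense_date missing")
    return PrescriptionRecord(
        person_id=_nonempty(row.person_id, "person_id"), dispense_date=d, atc_code=atc
    )


def _parse_discharge_row(row) -> DischargeRecord:
    adm = _parse_date(row.admission_date)
    dis = _parse_date(row.discharge_date)
    if adm is None or dis is None:
        raise ValueError("admission/discharge date missing")
    if adm > dis:
        raise ValueError("admission_date after discharge_date")
    dxs = []
    for name in ("dx1", "dx2", "dx3", "dx4", "dx5", "dx6"):
        v = str(getattr(row, name)).strip()
        if v and v.lower() not in ("nan", "none"):
            dxs.append(v)
    if not 1 <= len(dxs) <= 6:
        raise ValueError(f"{len(dxs)} diagnosis codes (need 1-6)")
    return DischargeRecord(
        person_id=_nonempty(row.person_id, "person_id"),
        admission_date=adm,
        discharge_date=dis,
        diagnoses=tuple(dxs),
    )


def _parse_exemption_row(row) -> ExemptionRecord:
    d = _parse_date(row.start_date)
    if d is None:
        raise ValueError("start_date missing")
    return ExemptionRecord(
        person_id=_nonempty(row.person_id, "person_id"),
        exemption_code=_nonempty(row.exemption_code, "exemption_code"),
        start_date=d,
    )


def _iso(d: date | None) -> str:
    return "" if d is None else d.isoformat()


def records_to_frame(records: Sequence, source_kind: str) -> pd.DataFrame:
    """Convert typed records back into the documented flat table."""
    rows: list[dict] = []
    if source_kind == "registry":
        for r in records:
            rows.append(
                {
                    "person_id": r.person_id,
                    "sex": r.sex,
                    "birth_date": _iso(r.birth_date),
                    "death_date": _iso(r.death_date),
                    "municipality_id": r.municipality_id,
                    "residency_start": _iso(r.residency_start),
                    "residency_end": _iso(r.residency_end),
                }
            )
    elif source_kind == "prescriptions":
        for r in records:
            rows.append(
                {
                    "person_id": r.person_id,
                    "dispense_date": _iso(r.dispense_date),
                    "atc_code": r.atc_code,
                }
            )
    elif source_kind == "discharges":
        for r in records:
            row = {
                "person_id": r.person_id,
                "admission_date": _iso(r.admission_date),
                "discharge_date": _iso(r.discharge_date),
            }
            for k in range(6):
                row[f"dx{k + 1}"] = r.diagnoses[k] if k < len(r.diagnoses) else ""
            rows.append(row)
    elif source_kind == "exemptions":
        for r in records:
            rows.append(
                {
                    "person_id": r.person_id,
                    "exemption_code": r.exemption_code,
                    "start_date": _iso(r.start_date),
                }
            )
    else:
        raise ValueError(f"unknown source_kind {source_kind!r}")
    return pd.DataFrame(rows, columns=list(_COLUMNS[source_kind]))


def write_source(path: str | Path, records: Sequence, source_kind: str) -> None:
    df = records_to_frame(records, source_kind)
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def build_histories(
    persons: Iterable[PersonRecord],
    prescriptions: Iterable[PrescriptionRecord] = (),
    discharges: Iterable[DischargeRecord] = (),
    exemptions: Iterable[ExemptionRecord] = (),
) -> tuple[dict[str, EventHistory], dict[str, int]]:
    """Assemble per-person event histories keyed by ``person_id``.

    Every registry person gets a (possibly empty) history.  Events whose
    ``person_id`` is absent from the registry are dropped and counted in
    the returned orphan tally — administrative extracts are known-dirty.
    """
    histories: dict[str, EventHistory] = {}
    for p in persons:
        if p.person_id in histories:
            raise ValueError(f"duplicate person_id {p.person_id!r} in registry")
        histories[p.person_id] = EventHistory(person=p)
    orphans = {"prescriptions": 0, "discharges": 0, "exemptions": 0}
    for r in prescriptions:
        h = histories.get(r.person_id)
        if h is None:
            orphans["prescriptions"] += 1
        else:
            h.prescriptions.append(r)
    for r in discharges:
        h = histories.get(r.person_id)
        if h is None:
            orphans["discharges"] += 1
        else:
            h.discharges.append(r)
    for r in exemptions:
        h = histories.get(r.person_id)
        if h is None:
            orphans["exemptions"] += 1
        else:
            h.exemptions.append(r)
    for h in histories.values():
        h.sort()
    return histories, orphans
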