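"""Municipality-level aggregation and GeoJSON/CSV export.

Raw (unsmoothed) municipal rates: with small denominators these are
noisy — interpret single-municipality estimates with care.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from neuroclaims.identify import GROUPS, CaseRecord
from neuroclaims.records import PersonRecord

__all__ = ["municipal_rates", "export_geojson", "GeometryMismatch"]


class GeometryMismatch(ValueError):
    def __init__(self, missing_ids: list[str]):
        self.missing_ids = missing_ids
        super().__init__(f"no geometry for municipality ids: {missing_ids}")


def municipal_rates(
    cases: Sequence[CaseRecord],
    persons: Sequence[PersonRecord],
    reference_year: int,
    min_age: int = 40,
) -> pd.DataFrame:
    """Per-municipality, per-group counts and per-1,000 rates.

    Denominator: residents alive on Dec 31 of the reference year aged
    at least ``min_age``.  Zero-population municipalities are dropped
    with a warning column-free; a case in an unknown municipality is an
    error.
    """
    ref_end = date(reference_year, 12, 31)
    muni_of: dict[str, str] = {}
    pop: dict[str, int] = {}
    for p in persons:
        muni_of[p.person_id] = p.municipality_id
        if p.alive_on(ref_end) and p.resident_on(ref_end) and p.age_on(ref_end) >= min_age:
            pop[p.municipality_id] = pop.get(p.municipality_id, 0) + 1

    counts: dict[tuple[str, str], dict[str, int]] = {}
    for c in cases:
        muni = muni_of.get(c.person_id)
        if muni is None:
            raise ValueError(f"case {c.person_id} has no municipality in the registry")
        cell = counts.setdefault((muni, c.group), {"cases": 0, "new_cases": 0})
        cell["cases"] += 1
        if c.incident:
            cell["new_cases"] += 1

    rows = []
    for muni in sorted(set(muni_of.values())):
        P = pop.get(muni, 0)
        if P == 0:
            continue
        for group in GROUPS:
            cell = counts.get((muni, group), {"cases": 0, "new_cases": 0})
            rows.append(
                {
                    "municipality_id": muni,
                    "group": group,
                    "population": P,
                    "cases": cell["cases"],
                    "prevalence": 1000.0 * cell["cases"] / P,
                    "new_cases": cell["new_cases"],
                    "incidence": 1000.0 * cell["new_cases"] / P,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "municipality_id", "group", "population", "cases",
            "prevalence", "new_cases", "incidence",
        ],
    )


def export_geojson(
    rates: pd.DataFrame,
    path: str | Path,
    geometry: Mapping[str, object] | str | Path | None = None,
) -> Path:
    """Write municipal rates as a GeoJSON FeatureCollection, or plain
    CSV when no geometry is supplied.

    ``geometry`` maps municipality_id to a shapely geometry (or is a
    GeoJSON file whose features carry a ``municipality_id`` property).
    Missing geometries raise :class:`GeometryMismatch` naming the ids.
    """
    path = Path(path)
    if geometry is None:
        out = path if path.suffix == ".csv" else path.with_suffix(".csv")
        rates.to_csv(out, index=False)
        return out

    from shapely.geometry import mapping, shape

    if isinstance(geometry, (str, Path)):
        fc = json.loads(Path(geometry).read_text())
        geometry = {
            f["properties"]["municipality_id"]: shape(f["geometry"]) for f in fc["features"]
        }

    munis = sorted(rates["municipality_id"].unique())
    missing = [m for m in munis if m not in geometry]
    if missing:
        raise GeometryMismatch(missing)

    features = []
    for muni in munis:
        sub = rates[rates["municipality_id"] == muni]
        props: dict = {"municipality_id": muni, "population": int(sub["population"].iloc[0])}
        for row in sub.itertuples(index=False):
            props[f"{row.group}_prevalence"] = row.prevalence
            props[f"{row.group}_incidence"] = row.incidence
            props[f"{row.group}_cases"] = int(row.cases)
        features.append(
            {"type": "Feature", "geometry": mapping(geometry[muni]), "properties": props}
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
    return path
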