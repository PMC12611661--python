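"""Synthetic region generator for the four linked administrative sources.

Plants an age/sex-structured population with known disease status
(parkinsonism, dementia, or both), then emits the prescription,
discharge and exemption streams a real claims extract would contain:
tracer-drug repetition for treated cases, optional hospital and
exemption evidence, proxy-drug *confounders* among non-cases (a share
of whom carry psychiatric labels), deaths, and municipality assignment
with log-uniform town sizes.  The planted truth table is the oracle for
every downstream recovery test.

With detection probabilities at 1 and no confounders, adjudication of
the generated streams recovers the planted case set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from neuroclaims.rates import AGE_CLASSES, AgeClassScheme, DEFAULT_SCHEME
from neuroclaims.records import (
    DischargeRecord,
    ExemptionRecord,
    PersonRecord,
    PrescriptionRecord,
    records_to_frame,
)

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "default_age_sex_structure",
    "generate_population",
    "emit_events",
    "write_fixture",
    "simulate",
]

STATUSES = ("none", "parkinsonism", "dementia", "both")

# generator-side drug tables; codes fall under the default codebook prefixes
_PARK_DRUGS = (("N04BA02", 0.55), ("N04BC05", 0.30), ("N04BB01", 0.10), ("N04AA02", 0.05))
_DEM_SYMPTOMATIC = (("N06DA02", 0.50), ("N06DA03", 0.30), ("N06DX01", 0.20))
_DEM_PROXY = (
    ("N05AH04", 0.45),  # quetiapine
    ("N05AH03", 0.10),  # olanzapine
    ("N05AX08", 0.04),  # risperidone
    ("N06AX05", 0.29),  # trazodone
    ("N06AX11", 0.12),  # mirtazapine
)
_DEM_ICD9 = ("2900", "29410", "3310")
_PSYCH_ICD9 = ("2952", "29620")
_PARK_EXEMPTION = "038"
_DEM_EXEMPTION = "011"
_PSYCH_EXEMPTION = "044"


def default_age_sex_structure(male_share: float = 0.48) -> dict[str, dict[str, float]]:
    """Plausible 40+ age structure (shares sum to 1 over class x sex)."""
    class_shares = {
        "40-44": 0.105, "45-49": 0.120, "50-54": 0.125, "55-59": 0.120,
        "60-64": 0.105, "65-69": 0.095, "70-74": 0.090, "75-79": 0.080,
        "80-84": 0.070, "85-89": 0.050, "90-94": 0.028, "95-99": 0.010,
        "100+": 0.002,
    }
    return {
        cls: {"male": s * male_share, "female": s * (1.0 - male_share)}
        for cls, s in class_shares.items()
    }


def _per_class(value: float | Mapping[str, float], name: str) -> np.ndarray:
    if isinstance(value, Mapping):
        missing = [c for c in AGE_CLASSES if c not in value]
        if missing:
            raise ValueError(f"{name}: missing classes {missing}")
        arr = np.array([float(value[c]) for c in AGE_CLASSES])
    else:
        arr = np.full(len(AGE_CLASSES), float(value))
    if (arr < 0).any():
        raise ValueError(f"{name}: rates must be >= 0")
    return arr


@dataclass
class SimulationConfig:
    n_persons: int = 10_000
    reference_year: int = 2021
    study_start_year: int = 2016
    seed: int = 0
    age_sex_structure: dict[str, dict[str, float]] = field(
        default_factory=default_age_sex_structure
    )
    # per-1,000 planted rates, scalar (flat) or per age class
    planted_prevalence: dict = field(
        default_factory=lambda: {"parkinsonism": 13.0, "dementia": 48.0}
    )
    planted_annual_incidence: dict = field(
        default_factory=lambda: {"parkinsonism": 2.8, "dementia": 7.5}
    )
    comorbidity_fraction: float = 0.25
    confounder_fraction: float = 0.02
    psychiatric_label_fraction: float = 0.5
    dem_symptomatic_share: float = 0.10
    detection: dict = field(
        default_factory=lambda: {"p_rx": 1.0, "p_hdr": 0.15, "p_exemption": 0.20}
    )
    rx_repeat: dict = field(default_factory=lambda: {3: 0.3, 4: 0.4, 6: 0.3})
    mortality: dict = field(default_factory=lambda: {"case": 0.05, "noncase": 0.01})
    n_municipalities: int = 10
    prevalent_onset_span_years: int = 10

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.study_start_year > self.reference_year:
            raise ValueError("study window ill-ordered")
        total = sum(s for d in self.age_sex_structure.values() for s in d.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"age/sex shares sum to {total}, expected 1")
        for k, v in self.detection.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"detection[{k}]={v} outside [0,1]")
        for frac in (self.comorbidity_fraction, self.confounder_fraction,
                     self.psychiatric_label_fraction, self.dem_symptomatic_share):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if any(int(k) < 2 for k in self.rx_repeat):
            raise ValueError("rx_repeat counts must be >= 2 (repeated use)")
        if not np.isclose(sum(self.rx_repeat.values()), 1.0, atol=1e-6):
            raise ValueError("rx_repeat probabilities must sum to 1")
        if self.n_municipalities <= 0:
            raise ValueError("need at least one municipality")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "rx_repeat" in data:
            data["rx_repeat"] = {int(k): float(v) for k, v in data["rx_repeat"].items()}
        return cls(**data)


@dataclass
class SimulatedData:
    persons: list[PersonRecord]
    prescriptions: list[PrescriptionRecord]
    discharges: list[DischargeRecord]
    exemptions: list[ExemptionRecord]
    truth: pd.DataFrame
    config: SimulationConfig


def _class_bounds(cls: str) -> tuple[int, int]:
    if cls.endswith("+"):
        lo = int(cls[:-1])
        return lo, lo + 4
    lo, hi = cls.split("-")
    return int(lo), int(hi)


def _random_day(rng: np.random.Generator, year: int) -> date:
    return date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))


def generate_population(
    cfg: SimulationConfig, scheme: AgeClassScheme = DEFAULT_SCHEME
) -> tuple[list[PersonRecord], pd.DataFrame]:
    """Draw the registry and its planted ground truth.

    Truth columns: person_id, sex, age_class, true_status,
    park_onset_year, dem_onset_year, onset_year, death_year.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    ref = cfg.reference_year
    n = cfg.n_persons

    cells = [(cls, sex) for cls in AGE_CLASSES for sex in ("male", "female")]
    probs = np.array([cfg.age_sex_structure.get(cls, {}).get(sex, 0.0) for cls, sex in cells])
    cell_idx = rng.choice(len(cells), size=n, p=probs / probs.sum())
    cls_idx = cell_idx // 2
    sexes = np.where(cell_idx % 2 == 0, "male", "female")

    bounds = np.array([_class_bounds(c) for c in AGE_CLASSES])
    ages = rng.integers(bounds[cls_idx, 0], bounds[cls_idx, 1] + 1)

    prev_park = _per_class(cfg.planted_prevalence.get("parkinsonism", 0.0), "prevalence.park")
    prev_dem = _per_class(cfg.planted_prevalence.get("dementia", 0.0), "prevalence.dem")
    inc_park = _per_class(cfg.planted_annual_incidence.get("parkinsonism", 0.0), "incidence.park")
    inc_dem = _per_class(cfg.planted_annual_incidence.get("dementia", 0.0), "incidence.dem")

    p_park = prev_park[cls_idx] / 1000.0
    p_dem = prev_dem[cls_idx] / 1000.0
    u = rng.random((4, n))
    park_prev = u[0] < p_park
    # comorbidity_fraction governs dementia among parkinsonism cases,
    # capped by the planted marginal dementia prevalence; the remainder
    # is tuned so that marginal stays at its planted value
    cf = np.where(
        p_park > 0, np.minimum(cfg.comorbidity_fraction, p_dem / np.maximum(p_park, 1e-12)), 0.0
    )
    cf = np.minimum(cf, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_dem_rest = np.clip((p_dem - p_park * cf) / np.maximum(1.0 - p_park, 1e-12), 0.0, 1.0)
    dem_prev = np.where(park_prev, u[1] < cf, u[1] < p_dem_rest)

    park_inc = ~park_prev & (u[2] < inc_park[cls_idx] / 1000.0)
    dem_inc = ~dem_prev & (u[3] < inc_dem[cls_idx] / 1000.0)
    park = park_prev | park_inc
    dem = dem_prev | dem_inc
    any_case = park | dem

    span = cfg.prevalent_onset_span_years
    onset_prev_park = rng.integers(ref - span, ref, size=n)
    onset_prev_dem = rng.integers(ref - span, ref, size=n)
    park_onset = np.where(park_inc, ref, onset_prev_park)
    dem_onset = np.where(dem_inc, ref, onset_prev_dem)

    mort_case = _per_class(cfg.mortality.get("case", 0.0), "mortality.case")
    mort_non = _per_class(cfg.mortality.get("noncase", 0.0), "mortality.noncase")
    p_death = np.where(any_case, mort_case[cls_idx], mort_non[cls_idx])
    dies = rng.random(n) < p_death
    death_days = rng.integers(0, 365, size=n)

    muni_sizes = np.exp(rng.uniform(np.log(50.0), np.log(50_000.0), cfg.n_municipalities))
    muni_idx = rng.choice(cfg.n_municipalities, size=n, p=muni_sizes / muni_sizes.sum())

    birth_days = rng.integers(0, 365, size=n)
    window_start = date(cfg.study_start_year, 1, 1)

    persons: list[PersonRecord] = []
    rows: list[dict] = []
    for i in range(n):
        pid = f"P{i:07d}"
        birth = date(ref - int(ages[i]), 1, 1) + timedelta(days=int(birth_days[i]))
        death = _random_day_offset(ref, int(death_days[i])) if dies[i] else None
        status = _status(park[i], dem[i])
        onsets = []
        if park[i]:
            onsets.append(int(park_onset[i]))
        if dem[i]:
            onsets.append(int(dem_onset[i]))
        persons.append(
            PersonRecord(
                person_id=pid,
                sex=str(sexes[i]),
                birth_date=birth,
                death_date=death,
                municipality_id=f"M{int(muni_idx[i]):03d}",
                residency_start=window_start,
                residency_end=death,
            )
        )
        rows.append(
            {
                "person_id": pid,
                "sex": str(sexes[i]),
                "age_class": AGE_CLASSES[int(cls_idx[i])],
                "true_status": status,
                "park_onset_year": int(park_onset[i]) if park[i] else pd.NA,
                "dem_onset_year": int(dem_onset[i]) if dem[i] else pd.NA,
                "onset_year": min(onsets) if onsets else pd.NA,
                "death_year": death.year if death else pd.NA,
            }
        )
    truth = pd.DataFrame(rows).astype(
        {"park_onset_year": "Int64", "dem_onset_year": "Int64",
         "onset_year": "Int64", "death_year": "Int64"}
    )
    return persons, truth


def _random_day_offset(year: int, day: int) -> date:
    return date(year, 1, 1) + timedelta(days=day)


def _status(park: bool, dem: bool) -> str:
    if park and dem:
        return "both"
    if park:
        return "parkinsonism"
    if dem:
        return "dementia"
    return "none"


def _choice(rng: np.random.Generator, table) -> str:
    codes = [c for c, _ in table]
    p = np.array([w for _, w in table])
    return codes[int(rng.choice(len(codes), p=p / p.sum()))]


def _sample_repeat(rng: np.random.Generator, rx_repeat: Mapping[int, float]) -> int:
    counts = sorted(rx_repeat)
    p = np.array([rx_repeat[c] for c in counts])
    return int(counts[int(rng.choice(len(counts), p=p / p.sum()))])


def emit_events(
    persons: list[PersonRecord],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
) -> tuple[list[PrescriptionRecord], list[DischargeRecord], list[ExemptionRecord]]:
    """Generate the three event streams implied by the planted truth."""
    rng = np.random.default_rng([cfg.seed, 1])
    ref, start = cfg.reference_year, cfg.study_start_year
    p_rx = cfg.detection["p_rx"]
    p_hdr = cfg.detection["p_hdr"]
    p_ex = cfg.detection["p_exemption"]

    by_id = {p.person_id: p for p in persons}
    rx: list[PrescriptionRecord] = []
    hdr: list[DischargeRecord] = []
    ex: list[ExemptionRecord] = []

    def yearly_rx(pid: str, drug: str, first_year: int, death: date | None) -> None:
        last = ref if death is None else min(ref, death.year)
        for y in range(max(first_year, start), last + 1):
            if rng.random() >= p_rx:
                continue
            k = _sample_repeat(rng, cfg.rx_repeat)
            days = np.sort(rng.integers(0, 365, size=k))
            for d in days:
                when = date(y, 1, 1) + timedelta(days=int(d))
                if death is not None and when > death:
                    continue
                rx.append(PrescriptionRecord(pid, when, drug))

    def one_discharge(pid: str, year: int, dx: str, death: date | None) -> None:
        adm = _random_day(rng, year)
        if death is not None and adm > death:
            adm = death
        hdr.append(DischargeRecord(pid, adm, adm + timedelta(days=int(rng.integers(1, 15))),
                                   (dx,)))

    def one_exemption(pid: str, year: int, code: str, death: date | None) -> None:
        when = _random_day(rng, year)
        if death is not None and when > death:
            when = death
        ex.append(ExemptionRecord(pid, code, when))

    for row in truth.itertuples(index=False):
        person = by_id[row.person_id]
        death = person.death_date
        status = row.true_status

        if status in ("parkinsonism", "both"):
            onset = int(row.park_onset_year)
            yearly_rx(row.person_id, _choice(rng, _PARK_DRUGS), onset, death)
            if rng.random() < p_ex:
                one_exemption(row.person_id, max(onset, start), _PARK_EXEMPTION, death)

        if status in ("dementia", "both"):
            onset = int(row.dem_onset_year)
            if rng.random() < cfg.dem_symptomatic_share:
                drug = _choice(rng, _DEM_SYMPTOMATIC)
            else:
                drug = _choice(rng, _DEM_PROXY)
            yearly_rx(row.person_id, drug, onset, death)
            if rng.random() < p_hdr:
                one_discharge(row.person_id, max(onset, start), _choice_item(rng, _DEM_ICD9),
                              death)
            if rng.random() < p_ex:
                one_exemption(row.person_id, max(onset, start), _DEM_EXEMPTION, death)

        if status == "none" and rng.random() < cfg.confounder_fraction:
            first_year = int(rng.integers(start, ref + 1))
            drug = _choice(rng, (("N05AH04", 0.5), ("N06AX05", 0.3), ("N06AX11", 0.2)))
            # confounders always reach the repetition threshold so the
            # planted false-positive rate is exactly confounder_fraction
            last = ref if death is None else min(ref, death.year)
            for y in range(first_year, last + 1):
                k = _sample_repeat(rng, cfg.rx_repeat)
                for d in np.sort(rng.integers(0, 365, size=k)):
                    when = date(y, 1, 1) + timedelta(days=int(d))
                    if death is None or when <= death:
                        rx.append(PrescriptionRecord(row.person_id, when, drug))
            if rng.random() < cfg.psychiatric_label_fraction:
                label_year = int(rng.integers(start, ref + 1))
                if rng.random() < 0.5:
                    one_exemption(row.person_id, label_year, _PSYCH_EXEMPTION, death)
                else:
                    one_discharge(row.person_id, label_year, _choice_item(rng, _PSYCH_ICD9),
                                  death)

    rx.sort(key=lambda r: (r.person_id, r.dispense_date))
    hdr.sort(key=lambda r: (r.person_id, r.admission_date))
    ex.sort(key=lambda r: (r.person_id, r.start_date))
    return rx, hdr, ex


def _choice_item(rng: np.random.Generator, items: tuple[str, ...]) -> str:
    return items[int(rng.integers(0, len(items)))]


def simulate(cfg: SimulationConfig) -> SimulatedData:
    persons, truth = generate_population(cfg)
    rx, hdr, ex = emit_events(persons, truth, cfg)
    return SimulatedData(persons, rx, hdr, ex, truth, cfg)


def write_fixture(out_dir: str | Path, data: SimulatedData) -> dict[str, Path]:
    """Write the four source CSVs plus truth.csv and the config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, recs in (
        ("registry", data.persons),
        ("prescriptions", data.prescriptions),
        ("discharges", data.discharges),
        ("exemptions", data.exemptions),
    ):
        p = out / f"{kind}.csv"
        records_to_frame(recs, kind).to_csv(p, index=False)
        paths[kind] = p
    truth_path = out / "truth.csv"
    data.truth[["person_id", "true_status", "onset_year", "death_year"]].to_csv(
        truth_path, index=False
    )
    paths["truth"] = truth_path
    cfg_path = out / "sim_config.yaml"
    data.config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths
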