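"""Crude, age-specific and directly standardized rates with their CIs.

Conventions (matching the presentation of regional burden tables):

* rates are per 1,000 and rounded half-up to 2 decimals for display;
* the denominator of every crude figure — prevalence, incidence *and*
  mortality — is the full resident population of the age range;
* Wilson score intervals for crude and age-specific rates; percentile
  bootstrap (person resampling) for standardized rates;
* incidence rate ratios carry log-normal Poisson intervals.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AGE_CLASSES",
    "AgeClassScheme",
    "StandardPopulation",
    "RateEstimate",
    "IrrEstimate",
    "load_standard",
    "round_half_up",
    "crude_rate",
    "wilson_ci",
    "age_adjusted_rate",
    "bootstrap_ci_adjusted",
    "bootstrap_ci_adjusted_counts",
    "irr",
    "irr_ci",
    "rate_table",
]

AGE_CLASSES: tuple[str, ...] = (
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-89",
    "90-94",
    "95-99",
    "100+",
)


@dataclass(frozen=True)
class AgeClassScheme:
    """Contiguous 5-year classes, open-topped, lower bound 40."""

    classes: tuple[str, ...] = AGE_CLASSES
    lower_bound: int = 40

    def class_of(self, age: int) -> str:
        if age < self.lower_bound:
            raise ValueError(f"age {age} below scheme lower bound {self.lower_bound}")
        idx = min((age - self.lower_bound) // 5, len(self.classes) - 1)
        return self.classes[idx]

    def at_least(self, min_age: int) -> tuple[str, ...]:
        i = (min_age - self.lower_bound) // 5
        return self.classes[i:]


DEFAULT_SCHEME = AgeClassScheme()


@dataclass(frozen=True)
class StandardPopulation:
    name: str
    weights: Mapping[str, float]  # age_class -> share, sums to 1 over classes
    renormalized: bool = False

    def restrict(self, classes: Sequence[str]) -> "StandardPopulation":
        w = {c: self.weights[c] for c in classes}
        total = sum(w.values())
        if total <= 0:
            raise ValueError("no positive standard weight over requested classes")
        return StandardPopulation(
            name=self.name, weights={c: v / total for c, v in w.items()}, renormalized=True
        )


_STANDARD_FILES = {
    "who": ("WHO_2000_2025", "who_std.csv"),
    "eurostat": ("EUROSTAT_ESP", "esp_std.csv"),
}


def load_standard(name: str) -> StandardPopulation:
    """Load a bundled standard population (``who`` or ``eurostat``),
    normalized over all its age classes."""
    key = name.lower()
    if key in ("who_2000_2025",):
        key = "who"
    if key in ("eurostat_esp", "esp", "esp2013"):
        key = "eurostat"
    if key not in _STANDARD_FILES:
        raise ValueError(f"unknown standard population {name!r}")
    label, fname = _STANDARD_FILES[key]
    with importlib.resources.files("neuroclaims.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh)
    total = df["weight"].sum()
    weights = dict(zip(df["age_class"], df["weight"] / total))
    return StandardPopulation(name=label, weights=weights)


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateEstimate:
    kind: str  # prevalence | incidence | mortality
    scope: str  # crude | age_specific | adjusted
    numerator: int | None
    denominator: int | None
    rate: float  # per 1,000
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str | None = None
    standard: str | None = None

    def rounded(self, ndigits: int = 2) -> tuple[float, float | None, float | None]:
        lo = None if self.ci_low is None else round_half_up(self.ci_low, ndigits)
        hi = None if self.ci_high is None else round_half_up(self.ci_high, ndigits)
        return round_half_up(self.rate, ndigits), lo, hi


@dataclass(frozen=True)
class IrrEstimate:
    irr: float
    ci_low: float
    ci_high: float
    rate_num: float
    rate_den: float
    cases_num: int | None = None
    cases_den: int | None = None
    label: str = ""


def _check_counts(n: int, P: int) -> None:
    if P <= 0:
        raise ValueError("population denominator must be positive")
    if not 0 <= n <= P:
        raise ValueError(f"count {n} outside [0, {P}]")


def crude_rate(n: int, P: int, kind: str = "prevalence", level: float = 0.95) -> RateEstimate:
    """Crude per-1,000 rate n/P with a Wilson score interval attached."""
    _check_counts(n, P)
    lo, hi = wilson_ci(n, P, level=level)
    return RateEstimate(
        kind=kind,
        scope="crude",
        numerator=n,
        denominator=P,
        rate=1000.0 * n / P,
        ci_low=lo,
        ci_high=hi,
        ci_method="wilson",
    )


def wilson_ci(n: int, P: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for the proportion n/P, scaled per 1,000."""
    _check_counts(n, P)
    lo, hi = proportion_confint(n, P, alpha=1.0 - level, method="wilson")
    point = 1000.0 * n / P
    # guard against ~1e-15 float spill at the p=0 / p=1 edges
    lo = min(max(1000.0 * float(lo), 0.0), point)
    hi = max(min(1000.0 * float(hi), 1000.0), point)
    return lo, hi


def _as_series(strat: pd.DataFrame | Mapping, col: str) -> pd.Series:
    if isinstance(strat, pd.DataFrame):
        return strat[col]
    raise TypeError("strat must be a DataFrame indexed by age class")


def age_adjusted_rate(
    strat: pd.DataFrame,
    std: StandardPopulation,
    numerator: str = "cases",
    kind: str = "prevalence",
) -> RateEstimate:
    """Direct standardization: per-1,000 weighted sum of class rates.

    ``strat`` is indexed by age class with a population column and the
    chosen numerator column; standard weights are renormalized over the
    classes present.
    """
    cases = _as_series(strat, numerator).astype(float)
    pop = _as_series(strat, "population").astype(float)
    std_r = std.restrict(list(strat.index))
    rate = 0.0
    for cls in strat.index:
        w = std_r.weights[cls]
        if w > 0 and pop[cls] <= 0:
            raise ValueError(f"empty population stratum {cls!r} with positive standard weight")
        if pop[cls] > 0:
            rate += (cases[cls] / pop[cls]) * w
    return RateEstimate(
        kind=kind,
        scope="adjusted",
        numerator=int(cases.sum()),
        denominator=int(pop.sum()),
        rate=1000.0 * rate,
        standard=std.name,
    )


def _adjusted_from_arrays(cases: np.ndarray, pop: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized adjusted rate for resampled class counts.

    Rows with empty classes renormalize the weights over non-empty ones
    (a resample can drop a tiny stratum entirely).
    """
    pop = pop.astype(float)
    nonempty = pop > 0
    rates = np.where(nonempty, np.divide(cases, pop, out=np.zeros_like(pop), where=nonempty), 0.0)
    weff = np.where(nonempty, w, 0.0)
    weff = weff / weff.sum(axis=-1, keepdims=True)
    return 1000.0 * (rates * weff).sum(axis=-1)


def bootstrap_ci_adjusted_counts(
    cases_by_class: Mapping[str, int] | pd.Series,
    pop_by_class: Mapping[str, int] | pd.Series,
    std: StandardPopulation,
    B: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the adjusted rate from class counts.

    Resampling n persons with replacement is equivalent in distribution
    to a multinomial draw over (age class x case-status) cells, which is
    what is done here; results are identical in law to person-level
    resampling but O(classes) per replicate.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    cases = pd.Series(cases_by_class).astype(int)
    pop = pd.Series(pop_by_class).astype(int).reindex(cases.index)
    n = int(pop.sum())
    if n == 0:
        raise ValueError("empty cohort")
    if int(cases.sum()) == 0:
        warnings.warn("degenerate bootstrap: no cases anywhere", stacklevel=2)
        return (0.0, 0.0)
    std_r = std.restrict(list(cases.index))
    w = np.array([std_r.weights[c] for c in cases.index])

    # cells: per class (case, non-case)
    probs = np.concatenate([cases.values, (pop - cases).values]).astype(float) / n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=B)
    k = len(cases)
    boot_cases = draws[:, :k]
    boot_pop = boot_cases + draws[:, k:]
    boot = _adjusted_from_arrays(boot_cases, boot_pop, w)
    alpha = 1.0 - level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def bootstrap_ci_adjusted(
    person_table: pd.DataFrame,
    std: StandardPopulation,
    B: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap CI from a person-level table with columns
    ``age_class`` and ``is_case``."""
    grouped = person_table.groupby("age_class", observed=True)["is_case"]
    cases = grouped.sum().astype(int)
    pop = grouped.size().astype(int)
    order = [c for c in AGE_CLASSES if c in cases.index] or list(cases.index)
    return bootstrap_ci_adjusted_counts(
        cases.reindex(order), pop.reindex(order), std, B=B, level=level, seed=seed
    )


def irr(rate_2: float, rate_1: float) -> float:
    """Ratio of two per-1,000 rates (year 2 relative to year 1)."""
    if rate_1 <= 0:
        raise ValueError("reference rate must be positive")
    return rate_2 / rate_1


def irr_ci(
    cases_2: int,
    pop_2: int,
    cases_1: int,
    pop_1: int,
    level: float = 0.95,
    label: str = "",
) -> IrrEstimate:
    """IRR with log-normal Poisson interval
    exp(ln IRR +/- z*sqrt(1/cases_2 + 1/cases_1))."""
    for c in (cases_2, cases_1):
        if c <= 0:
            raise ValueError("zero case count: log-normal IRR interval undefined "
                             "(no continuity correction by design)")
    if pop_1 <= 0 or pop_2 <= 0:
        raise ValueError("populations must be positive")
    r2 = 1000.0 * cases_2 / pop_2
    r1 = 1000.0 * cases_1 / pop_1
    point = r2 / r1
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1.0 / cases_2 + 1.0 / cases_1)
    return IrrEstimate(
        irr=point,
        ci_low=float(point * np.exp(-z * se)),
        ci_high=float(point * np.exp(z * se)),
        rate_num=r2,
        rate_den=r1,
        cases_num=cases_2,
        cases_den=cases_1,
        label=label,
    )


def _row(
    label: str,
    cases: int | None,
    new_cases: int | None,
    deaths: int | None,
    population: int | None,
    prev: RateEstimate | None,
    inc: RateEstimate | None,
    mort: RateEstimate | None,
) -> dict:
    def unpack(prefix: str, est: RateEstimate | None) -> dict:
        if est is None:
            return {prefix: np.nan, f"{prefix}_low": np.nan, f"{prefix}_high": np.nan}
        r, lo, hi = est.rounded()
        return {
            prefix: r,
            f"{prefix}_low": np.nan if lo is None else lo,
            f"{prefix}_high": np.nan if hi is None else hi,
        }

    out = {"stratum": label, "cases": cases, "new_cases": new_cases, "deaths": deaths,
           "population": population}
    out.update(unpack("prevalence", prev))
    out.update(unpack("incidence", inc))
    out.update(unpack("mortality", mort))
    return out


def stratified_counts(
    cases,
    persons,
    reference_year: int,
    scheme: AgeClassScheme = DEFAULT_SCHEME,
    group: str | None = None,
    sex: str | None = None,
    groups_as: str = "exact",
) -> pd.DataFrame:
    """Tabulate cases, new cases, deaths and population per age class.

    ``cases`` are adjudicated case records; ``persons`` the registry.
    Population = residents alive on Dec 31 of the reference year aged
    >= the scheme lower bound.  Deaths = identified cases who died in
    the reference year.  ``group`` filters to one adjudication group;
    with ``groups_as='contains'`` the 'both' group is pooled into each
    component disease (parkinsonism-any / dementia-any tabulations).
    """
    from datetime import date as _date

    ref_end = _date(reference_year, 12, 31)
    idx = {c: {"cases": 0, "new_cases": 0, "deaths": 0, "population": 0}
           for c in scheme.classes}
    by_id = {}
    for p in persons:
        by_id[p.person_id] = p
        if sex is not None and p.sex != sex:
            continue
        if p.alive_on(ref_end) and p.resident_on(ref_end):
            age = p.age_on(ref_end)
            if age >= scheme.lower_bound:
                idx[scheme.class_of(age)]["population"] += 1

    def in_group(g: str) -> bool:
        if group is None:
            return True
        if groups_as == "contains":
            return g == group or g == "both"
        return g == group

    for c in cases:
        if not in_group(c.group):
            continue
        p = by_id.get(c.person_id)
        if p is None or (sex is not None and p.sex != sex):
            continue
        age = p.age_on(ref_end)
        if age < scheme.lower_bound:
            continue
        cls = scheme.class_of(age)
        if c.died_in_reference_year:
            idx[cls]["deaths"] += 1
        if p.alive_on(ref_end) and p.resident_on(ref_end):
            idx[cls]["cases"] += 1
            if c.incident:
                idx[cls]["new_cases"] += 1
    return pd.DataFrame.from_dict(idx, orient="index").rename_axis("age_class")


def rate_table(
    strat: pd.DataFrame,
    standards: Iterable[StandardPopulation] = (),
    scheme: AgeClassScheme = DEFAULT_SCHEME,
    restrict_min_ages: Sequence[int] = (65,),
    bootstrap_B: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full burden table: one row per age class plus crude and adjusted
    summary rows, with 65+-restricted variants.

    ``strat`` is indexed by age class with columns ``cases``,
    ``new_cases``, ``deaths``, ``population``.  When ``seed`` is given,
    adjusted rows get bootstrap CIs (``bootstrap_B`` resamples).
    """
    strat = strat.reindex([c for c in scheme.classes if c in strat.index])
    rows: list[dict] = []

    def crude_block(sub: pd.DataFrame, label: str) -> None:
        P = int(sub["population"].sum())
        n, m, d = (int(sub[c].sum()) for c in ("cases", "new_cases", "deaths"))
        rows.append(
            _row(
                label, n, m, d, P,
                crude_rate(n, P, "prevalence"),
                crude_rate(m, P, "incidence"),
                crude_rate(d, P, "mortality"),
            )
        )

    def adjusted_block(sub: pd.DataFrame, std: StandardPopulation, label: str) -> None:
        # empty strata get zero weight (renormalized) rather than erroring:
        # small fixtures routinely lack centenarians
        sub = sub[sub["population"] > 0]
        rng = np.random.default_rng(seed) if seed is not None else None
        ests = {}
        for kind, col in (("prevalence", "cases"), ("incidence", "new_cases"),
                          ("mortality", "deaths")):
            est = age_adjusted_rate(sub, std, numerator=col, kind=kind)
            if rng is not None and int(sub[col].sum()) > 0:
                lo, hi = bootstrap_ci_adjusted_counts(
                    sub[col], sub["population"], std, B=bootstrap_B, seed=rng
                )
                est = RateEstimate(
                    kind=kind, scope="adjusted", numerator=est.numerator,
                    denominator=est.denominator, rate=est.rate, ci_low=lo, ci_high=hi,
                    ci_method="bootstrap", standard=std.name,
                )
            ests[kind] = est
        rows.append(
            _row(label, None, None, None, None,
                 ests["prevalence"], ests["incidence"], ests["mortality"])
        )

    for cls in strat.index:
        P = int(strat.loc[cls, "population"])
        n, m, d = (int(strat.loc[cls, c]) for c in ("cases", "new_cases", "deaths"))
        rows.append(
            _row(
                cls, n, m, d, P,
                crude_rate(n, P, "prevalence") if P else None,
                crude_rate(m, P, "incidence") if P else None,
                crude_rate(d, P, "mortality") if P else None,
            )
        )

    crude_block(strat, "crude")
    for std in standards:
        adjusted_block(strat, std, f"adjusted_{std.name}")
    for min_age in restrict_min_ages:
        keep = [c for c in scheme.at_least(min_age) if c in strat.index]
        sub = strat.loc[keep]
        crude_block(sub, f"crude_{min_age}plus")
        for std in standards:
            adjusted_block(sub, std, f"adjusted_{min_age}plus_{std.name}")

    return pd.DataFrame(rows)
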