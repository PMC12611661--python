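"""Configurable code sets driving case adjudication.

The exact regional code lists are deployment-specific, so everything is
a plain, editable configuration object with documented defaults:

* parkinsonism — antiparkinsonian ATC prefixes (levodopa N04BA, dopamine
  agonists N04BC, plus other N04 subgroups) and exemption code 038;
* dementia — symptomatic anti-dementia drugs (N06DA, memantine
  N06DX01), dementia-related ICD-9 diagnoses, a dementia exemption, and
  the proxy criterion (antipsychotics N05A, trazodone N06AX05,
  mirtazapine N06AX11);
* psychiatric exclusions — schizophrenia/affective-psychosis ICD-9
  prefixes and the psychosis exemption, which veto proxy-only cases.

ICD-9 codes are compared after stripping dots, by prefix, so "294.1"
matches "29410" and "29411".
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["Codebook", "normalize_icd9", "DEFAULT_CODEBOOK"]


def normalize_icd9(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class Codebook:
    park_atc: frozenset[str] = frozenset({"N04BA", "N04BC", "N04BB", "N04BX", "N04AA"})
    park_exemption: frozenset[str] = frozenset({"038"})
    dementia_atc: frozenset[str] = frozenset({"N06DA", "N06DX01"})
    proxy_atc: frozenset[str] = frozenset({"N05A", "N06AX05", "N06AX11"})
    dementia_icd9: frozenset[str] = frozenset({"290", "294.1", "294.2", "331.0", "331.1", "331.82"})
    dementia_exemption: frozenset[str] = frozenset({"011"})
    psych_icd9: frozenset[str] = frozenset({"295", "296"})
    psych_exemption: frozenset[str] = frozenset({"044"})
    repeat_min_count: int = 2
    repeat_window_days: int = 365

    def __post_init__(self) -> None:
        if self.repeat_min_count < 2:
            raise ValueError("repeat_min_count must be >= 2 ('repeated' use)")
        if self.repeat_window_days < 1:
            raise ValueError("repeat_window_days must be positive")
        for name in (
            "park_atc",
            "park_exemption",
            "dementia_atc",
            "proxy_atc",
            "dementia_icd9",
            "psych_icd9",
        ):
            if not getattr(self, name):
                raise ValueError(f"codebook set {name} must be non-empty")
        # freeze normalized/uppercased views
        object.__setattr__(self, "park_atc", frozenset(c.upper() for c in self.park_atc))
        object.__setattr__(self, "dementia_atc", frozenset(c.upper() for c in self.dementia_atc))
        object.__setattr__(self, "proxy_atc", frozenset(c.upper() for c in self.proxy_atc))
        object.__setattr__(
            self, "dementia_icd9", frozenset(normalize_icd9(c) for c in self.dementia_icd9)
        )
        object.__setattr__(
            self, "psych_icd9", frozenset(normalize_icd9(c) for c in self.psych_icd9)
        )

    # -- serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {k: (sorted(v) if isinstance(v, frozenset) else v) for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in cls.__dataclass_fields__.values():
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = frozenset(str(x) for x in v) if isinstance(v, (list, set, tuple)) else v
        return cls(**kwargs)

    # -- matching helpers ----------------------------------------------
    def matches_atc(self, code: str, prefixes: frozenset[str]) -> bool:
        c = code.upper()
        return any(c.startswith(p) for p in prefixes)

    def matches_dementia_icd9(self, code: str) -> bool:
        c = normalize_icd9(code)
        return any(c.startswith(p) for p in self.dementia_icd9)

    def matches_psych_icd9(self, code: str) -> bool:
        c = normalize_icd9(code)
        return any(c.startswith(p) for p in self.psych_icd9)


DEFAULT_CODEBOOK = Codebook()
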