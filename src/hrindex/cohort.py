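"""Cohort domain model: risk factors, threshold-defined diseases, and
physiological states.

A subject is described by five common clinical risk factors (fasting plasma
glucose, total cholesterol, triglycerides, systolic and diastolic blood
pressure).  Each disease is defined purely by upper thresholds on a subset of
those factors: a subject has the disease as soon as *any* listed factor is at
or above its threshold.  With ``n`` diseases the cohort splits into ``2**n``
physiological states — the healthy state (no disease) plus every disease
combination — and all downstream density estimation is stratified by state.

The threshold comparison is ``>=``: a value sitting exactly on the clinical
threshold counts as diseased.  This is the convention the risk index relies
on (the per-factor risk is defined to vanish at the threshold).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError

__all__ = [
    "RiskFactor",
    "FACTOR_UNITS",
    "RiskFactorProfile",
    "DiseaseDefinition",
    "PhysiologicalState",
    "Cohort",
    "triple_h_diseases",
    "state_space",
    "assign_state",
    "partition_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_disease_config",
]


class RiskFactor(str, enum.Enum):
    """The five common risk factors shared by the Triple H diseases."""

    FPG = "FPG"      # fasting plasma glucose [mg/dL]
    T_CHO = "T_CHO"  # total cholesterol [mg/dL]
    TG = "TG"        # triglycerides [mg/dL]
    SBP = "SBP"      # systolic blood pressure [mmHg]
    DBP = "DBP"      # diastolic blood pressure [mmHg]


FACTOR_UNITS: dict[RiskFactor, str] = {
    RiskFactor.FPG: "mg/dL",
    RiskFactor.T_CHO: "mg/dL",
    RiskFactor.TG: "mg/dL",
    RiskFactor.SBP: "mmHg",
    RiskFactor.DBP: "mmHg",
}


@dataclass(frozen=True)
class RiskFactorProfile:
    """One subject's measurement vector over all five risk factors.

    ``extras`` carries covariates such as sex or age untouched; the risk
    index does not stratify by them.
    """

    subject_id: str
    values: Mapping[RiskFactor, float]
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f.value for f in RiskFactor if f not in self.values]
        if missing:
            raise InputError(
                f"subject {self.subject_id!r}: missing factor value(s) {missing}"
            )
        for factor, value in self.values.items():
            v = float(value)
            if not math.isfinite(v) or v <= 0:
                raise InputError(
                    f"subject {self.subject_id!r}: factor {factor.value} must be "
                    f"a positive finite number, got {value!r}"
                )

    def value(self, factor: RiskFactor) -> float:
        return float(self.values[factor])

    def shifted(self, deltas: Mapping[RiskFactor, float], floor: float) -> "RiskFactorProfile":
        """Return a copy with ``deltas`` added, clamped below at ``floor``."""
        new_values = {
            f: max(self.value(f) + float(deltas.get(f, 0.0)), floor)
            for f in RiskFactor
        }
        return RiskFactorProfile(self.subject_id, new_values, dict(self.extras))


@dataclass(frozen=True)
class DiseaseDefinition:
    """A named disease defined by upper thresholds on one or more factors.

    The disease is present when ANY rule fires, i.e. when some listed factor
    value is >= its threshold.
    """

    name: str
    rules: tuple[tuple[RiskFactor, float], ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise InputError(f"disease {self.name!r}: needs at least one threshold rule")
        for factor, threshold in self.rules:
            if not (float(threshold) > 0):
                raise InputError(
                    f"disease {self.name!r}: threshold for {factor.value} must be positive"
                )

    def is_present(self, profile: RiskFactorProfile) -> bool:
        for factor, threshold in self.rules:
            if factor not in profile.values:
                raise InputError(
                    f"subject {profile.subject_id!r}: missing value for factor "
                    f"{factor.value} required by disease {self.name!r}"
                )
            if profile.value(factor) >= float(threshold):
                return True
        return False


def triple_h_diseases() -> list[DiseaseDefinition]:
    """The default Triple H disease set with standard clinical thresholds."""
    return [
        DiseaseDefinition(
            "Hypertension",
            ((RiskFactor.SBP, 140.0), (RiskFactor.DBP, 90.0)),
        ),
        DiseaseDefinition(
            "Hyperlipidemia",
            ((RiskFactor.T_CHO, 200.0), (RiskFactor.TG, 200.0)),
        ),
        DiseaseDefinition(
            "Hyperglycemia",
            ((RiskFactor.FPG, 126.0),),
        ),
    ]


@dataclass(frozen=True)
class PhysiologicalState:
    """One of the ``2**n`` disease-combination states.

    ``index`` runs from 1 (healthy, empty disease set) to ``2**n``; the
    mapping subset <-> index is the binary code of the disease list order,
    offset by one.
    """

    index: int
    diseases: frozenset[str]
    label: str

    @property
    def is_healthy(self) -> bool:
        return not self.diseases


def _make_state(code: int, diseases: Sequence[DiseaseDefinition]) -> PhysiologicalState:
    present = tuple(d.name for k, d in enumerate(diseases) if (code >> k) & 1)
    label = " & ".join(present) if present else "Normal"
    return PhysiologicalState(index=code + 1, diseases=frozenset(present), label=label)


def state_space(diseases: Sequence[DiseaseDefinition]) -> list[PhysiologicalState]:
    """All ``2**n`` physiological states in index order (state 1 = healthy)."""
    return [_make_state(code, diseases) for code in range(2 ** len(diseases))]


def assign_state(
    profile: RiskFactorProfile, diseases: Sequence[DiseaseDefinition]
) -> PhysiologicalState:
    """Map a subject to its physiological state by thresholding.

    A subject carries a disease iff any of that disease's factor values is at
    or above the threshold; healthy iff strictly below every threshold.
    """
    code = 0
    for k, disease in enumerate(diseases):
        if disease.is_present(profile):
            code |= 1 << k
    return _make_state(code, diseases)


@dataclass(frozen=True)
class Cohort:
    """A non-empty collection of subject profiles with unique ids."""

    profiles: tuple[RiskFactorProfile, ...]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise InputError("cohort must contain at least one subject")
        ids = [p.subject_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)


def partition_cohort(
    cohort: Cohort, diseases: Sequence[DiseaseDefinition]
) -> dict[PhysiologicalState, list[RiskFactorProfile]]:
    """Split a cohort into the ``2**n`` states (empty buckets included).

    Every profile lands in exactly one bucket; the union of buckets is the
    cohort.
    """
    buckets: dict[PhysiologicalState, list[RiskFactorProfile]] = {
        s: [] for s in state_space(diseases)
    }
    for profile in cohort:
        buckets[assign_state(profile, diseases)].append(profile)
    return buckets


# ---------------------------------------------------------------------------
# CSV / JSON interfaces

_REQUIRED_COLUMNS = ["subject_id"] + [f.value for f in RiskFactor]
_OPTIONAL_COLUMNS = ["sex", "age"]


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a cohort table (``subject_id,FPG,T_CHO,TG,SBP,DBP[,sex,age]``)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"cannot parse cohort CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"cohort CSV {path}: missing column(s) {missing}")
    profiles = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        values = {}
        for factor in RiskFactor:
            raw = getattr(row, factor.value)
            try:
                v = float(raw)
            except (TypeError, ValueError) as exc:
                raise InputError(
                    f"cohort CSV {path} line {line_no}: non-numeric "
                    f"{factor.value} value {raw!r}"
                ) from exc
            if not math.isfinite(v) or v <= 0:
                raise InputError(
                    f"cohort CSV {path} line {line_no}: {factor.value} must be "
                    f"positive and finite, got {raw!r}"
                )
            values[factor] = v
        extras = {
            c: getattr(row, c) for c in _OPTIONAL_COLUMNS if c in df.columns
        }
        try:
            profiles.append(
                RiskFactorProfile(str(getattr(row, "subject_id")), values, extras)
            )
        except InputError as exc:
            raise InputError(f"cohort CSV {path} line {line_no}: {exc}") from exc
    return Cohort(tuple(profiles))


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the canonical CSV schema (UTF-8, '.' decimals)."""
    extra_cols = [
        c for c in _OPTIONAL_COLUMNS if any(c in p.extras for p in cohort)
    ]
    rows = []
    for p in cohort:
        row: dict[str, object] = {"subject_id": p.subject_id}
        row.update({f.value: p.value(f) for f in RiskFactor})
        row.update({c: p.extras.get(c) for c in extra_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS + extra_cols).to_csv(
        path, index=False
    )


def load_disease_config(source: str | Path | Iterable[Mapping]) -> list[DiseaseDefinition]:
    """Load disease definitions from JSON (path) or an already-parsed list.

    Schema: ``[{"name": str, "rules": [{"factor": str, "threshold": num}]}]``.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = list(source)
    if not isinstance(data, list) or not data:
        raise InputError("disease config must be a non-empty JSON list")
    diseases = []
    for entry in data:
        try:
            rules = tuple(
                (RiskFactor(rule["factor"]), float(rule["threshold"]))
                for rule in entry["rules"]
            )
            diseases.append(DiseaseDefinition(str(entry["name"]), rules))
        except (KeyError, ValueError) as exc:
            raise InputError(f"bad disease config entry {entry!r}: {exc}") from exc
    return diseases
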