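"""The health-risk index: per-factor density-ratio risk and its product.

For each risk factor ``i`` the cohort is stratified into the ``2**n``
physiological states and a KDE is fitted per state.  The per-factor risk at
a measurement ``t`` is the posterior-style ratio

    R_i(t) = f_healthy,i(t) / sum_s f_s,i(t)     for x_i <= t < y_i
    R_i(t) = 0                                   otherwise

where the sum runs over every state with a fitted density, ``y_i`` is the
lowest disease threshold governing factor ``i`` and ``x_i`` the smallest
value observed among healthy subjects.  Because the numerator is one of the
non-negative summands, R_i(t) is always in [0, 1].  The subject-level health
risk index is the product of the five per-factor risks; it is 1 for a
subject indistinguishable from the healthy stratum everywhere and exactly 0
as soon as any factor sits at or above a disease threshold.

The product implicitly treats the factors as independent; no correlation
adjustment is attempted.  The top of the healthy range is closed
(R_i(y_i) = 0), matching the >= disease convention of the cohort model.  By
default the bottom is closed too (strict mode: R_i(t) = 0 below x_i);
``extrapolate_low=True`` instead extends the density ratio below the
observed healthy minimum, for callers who do not want unusually *low*
values treated as maximal risk.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    DiseaseDefinition,
    PhysiologicalState,
    RiskFactor,
    RiskFactorProfile,
    assign_state,
    load_disease_config,
    partition_cohort,
    state_space,
    triple_h_diseases,
)
from .errors import InputError, PreconditionError
from .kde import FittedDensity, select_kernel

__all__ = [
    "RiskModel",
    "HealthRiskResult",
    "RiskCurve",
    "InterventionSummary",
    "build_risk_model",
    "component_risk",
    "health_risk_index",
    "index_from_components",
    "risk_curve",
    "intervention_effect",
    "score_cohort",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Minimum number of clamped factor values after an intervention shift.
VALUE_FLOOR = 1e-6


@dataclass(frozen=True)
class RiskModel:
    """The fitted grid of per-(state, factor) densities plus thresholds.

    ``densities`` maps ``(state_index, factor)`` to a FittedDensity; states
    with fewer than two training subjects carry no density and are dropped
    from the denominator.  ``healthy_ranges`` maps each factor to the
    interval ``[x_i, y_i]`` where the ratio is defined: ``y_i`` is the
    minimal disease threshold on that factor, ``x_i`` the minimum healthy
    observation.
    """

    densities: Mapping[tuple[int, RiskFactor], FittedDensity]
    diseases: tuple[DiseaseDefinition, ...]
    healthy_ranges: Mapping[RiskFactor, tuple[float, float]]
    extrapolate_low: bool = False
    selection_report: tuple[dict, ...] = field(default=(), compare=False)

    @property
    def states(self) -> list[PhysiologicalState]:
        return state_space(self.diseases)

    @property
    def healthy_state_index(self) -> int:
        return 1

    def factor_densities(self, factor: RiskFactor) -> list[FittedDensity]:
        """All retained state densities for a factor (denominator terms)."""
        return [
            d for (idx, f), d in self.densities.items() if f is factor
        ]


def build_risk_model(
    cohort: Cohort,
    diseases: Sequence[DiseaseDefinition] | None = None,
    *,
    bandwidth: float | str = "nrd0",
    extrapolate_low: bool = False,
    min_state_samples: int = 2,
) -> RiskModel:
    """Fit the full per-(state, factor) density grid from a cohort.

    Runs the kernel-selection procedure independently for every state and
    factor with at least ``min_state_samples`` subjects; sparser states are
    excluded from the risk-ratio denominator with a logged warning.  An
    empty healthy stratum is unrecoverable: the index is a ratio anchored on
    the healthy density.
    """
    diseases = tuple(diseases) if diseases is not None else tuple(triple_h_diseases())
    buckets = partition_cohort(cohort, diseases)
    by_index = {state.index: profiles for state, profiles in buckets.items()}
    healthy = by_index[1]
    if not healthy:
        raise PreconditionError(
            "no healthy subjects in cohort: the health-risk ratio is undefined"
        )
    if len(healthy) < 10:
        logger.warning(
            "only %d healthy subjects; density estimates will be unstable",
            len(healthy),
        )

    densities: dict[tuple[int, RiskFactor], FittedDensity] = {}
    report: list[dict] = []
    for state in state_space(diseases):
        profiles = by_index[state.index]
        if len(profiles) < min_state_samples:
            if profiles or state.index == 1:
                logger.warning(
                    "state %r has %d subject(s) (< %d); dropped from denominator",
                    state.label,
                    len(profiles),
                    min_state_samples,
                )
            continue
        for factor in RiskFactor:
            samples = [p.value(factor) for p in profiles]
            selection = select_kernel(samples, bandwidth)
            densities[(state.index, factor)] = selection.density
            report.append(
                {
                    "state_index": state.index,
                    "state": state.label,
                    "factor": factor.value,
                    "n": len(samples),
                    "bandwidth": selection.bandwidth,
                    "kernel": selection.kernel.value,
                    "scores": {k.value: v for k, v in selection.scores.items()},
                }
            )

    healthy_ranges: dict[RiskFactor, tuple[float, float]] = {}
    for factor in RiskFactor:
        thresholds = [
            float(th)
            for d in diseases
            for (f, th) in d.rules
            if f is factor
        ]
        y = min(thresholds) if thresholds else math.inf
        x = min(p.value(factor) for p in healthy)
        healthy_ranges[factor] = (x, y)

    return RiskModel(
        densities=densities,
        diseases=diseases,
        healthy_ranges=healthy_ranges,
        extrapolate_low=extrapolate_low,
        selection_report=tuple(report),
    )


def _risk_values(model: RiskModel, factor: RiskFactor, ts: np.ndarray) -> np.ndarray:
    """Vectorised per-factor risk over an array of measurement values."""
    x_lo, y_hi = model.healthy_ranges[factor]
    ts = np.asarray(ts, dtype=float)
    out = np.zeros_like(ts)
    in_range = ts < y_hi
    if not model.extrapolate_low:
        in_range &= ts >= x_lo
    if not np.any(in_range):
        return out
    pts = ts[in_range]
    healthy_density = model.densities.get((model.healthy_state_index, factor))
    if healthy_density is None:
        raise PreconditionError(
            f"model has no healthy-state density for factor {factor.value}"
        )
    num = np.asarray(healthy_density.evaluate(pts))
    den = np.zeros_like(num)
    for dens in model.factor_densities(factor):
        den += np.asarray(dens.evaluate(pts))
    ratio = np.zeros_like(num)
    positive = den > 0.0
    if not np.all(positive):
        logger.debug(
            "zero denominator at %d point(s) for %s; risk set to 0",
            int((~positive).sum()),
            factor.value,
        )
    ratio[positive] = num[positive] / den[positive]
    out[in_range] = ratio
    return out


def component_risk(model: RiskModel, factor: RiskFactor, t: float) -> float:
    """Per-factor health risk R_i(t) in [0, 1]; 0 at/above the threshold."""
    return float(_risk_values(model, factor, np.asarray([float(t)]))[0])


def index_from_components(components: Sequence[float]) -> float:
    """Combine per-factor risks into the subject index (their product)."""
    return float(np.prod(np.asarray(list(components), dtype=float)))


@dataclass(frozen=True)
class HealthRiskResult:
    """Per-subject scoring outcome: components, product index, state."""

    subject_id: str
    components: Mapping[RiskFactor, float]
    index: float
    state: PhysiologicalState

    def rounded(self, ndigits: int = 4) -> dict:
        """User-facing view with values rounded as in published tables."""
        return {
            "subject_id": self.subject_id,
            **{f.value: round(self.components[f], ndigits) for f in RiskFactor},
            "state": self.state.label,
            "index": round(self.index, ndigits),
        }


def health_risk_index(model: RiskModel, profile: RiskFactorProfile) -> HealthRiskResult:
    """Score one subject: the product of the five per-factor risks.

    Any factor at or above a disease threshold contributes a zero component,
    so every non-healthy subject gets index 0.
    """
    components = {
        factor: component_risk(model, factor, profile.value(factor))
        for factor in RiskFactor
    }
    return HealthRiskResult(
        subject_id=profile.subject_id,
        components=components,
        index=index_from_components(list(components.values())),
        state=assign_state(profile, model.diseases),
    )


def score_cohort(model: RiskModel, cohort: Cohort) -> pd.DataFrame:
    """Score every subject; one row each, components and index at 4 d.p."""
    rows = [health_risk_index(model, p).rounded() for p in cohort]
    cols = ["subject_id"] + [f.value for f in RiskFactor] + ["state", "index"]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class RiskCurve:
    """The per-factor risk evaluated on an increasing grid of values."""

    factor: RiskFactor
    grid: tuple[float, ...]
    values: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"factor": self.factor.value, "t": self.grid, "risk": self.values}
        )


def risk_curve(
    model: RiskModel,
    factor: RiskFactor,
    *,
    points: int = 512,
    pad: float = 0.05,
    lo: float | None = None,
    hi: float | None = None,
) -> RiskCurve:
    """Evaluate the per-factor risk on an even grid around the healthy range.

    Default grid: ``[x_i - pad*span, y_i + pad*span]`` with ``span = y_i -
    x_i``; values are clamped to [0, 1] (a no-op for the raw ratio, but kept
    as an explicit contract).
    """
    x_lo, y_hi = model.healthy_ranges[factor]
    if not math.isfinite(y_hi):
        # unbounded factor: span from the healthy training samples
        healthy = model.densities.get((model.healthy_state_index, factor))
        y_hi = max(healthy.samples) if healthy is not None else x_lo + 1.0
    span = max(y_hi - x_lo, np.finfo(float).eps)
    grid_lo = x_lo - pad * span if lo is None else float(lo)
    grid_hi = y_hi + pad * span if hi is None else float(hi)
    if not (grid_hi > grid_lo) or points < 2:
        raise InputError("curve grid must be increasing with at least 2 points")
    grid = np.linspace(grid_lo, grid_hi, int(points))
    values = np.clip(_risk_values(model, factor, grid), 0.0, 1.0)
    return RiskCurve(factor, tuple(float(g) for g in grid), tuple(map(float, values)))


@dataclass(frozen=True)
class InterventionSummary:
    """Before/after indices for healthy subjects under factor shifts.

    Two summary conventions are reported: the mean of per-subject relative
    changes (subjects whose before-index is 0 are excluded and counted), and
    the relative change of the mean index over all healthy subjects.
    """

    per_subject: pd.DataFrame = field(compare=False)
    mean_relative_change: float
    relative_change_of_means: float
    n_subjects: int
    n_excluded_zero: int
    deltas: Mapping[RiskFactor, float]


def intervention_effect(
    model: RiskModel,
    cohort: Cohort,
    deltas: Mapping[RiskFactor, float],
    *,
    floor: float = VALUE_FLOOR,
) -> InterventionSummary:
    """Evaluate the index change when factor values shift by ``deltas``.

    Only healthy subjects are evaluated (the index of diseased subjects is
    identically 0 before and after).  Shifted values that would become
    non-positive are clamped at ``floor`` with a warning.
    """
    for factor, d in deltas.items():
        if not math.isfinite(float(d)):
            raise InputError(f"delta for {factor.value} must be finite")
    rows = []
    n_clamped = 0
    for profile in cohort:
        if not assign_state(profile, model.diseases).is_healthy:
            continue
        before = health_risk_index(model, profile).index
        shifted = profile.shifted(deltas, floor)
        n_clamped += sum(
            1
            for f in RiskFactor
            if profile.value(f) + float(deltas.get(f, 0.0)) < floor
        )
        after = health_risk_index(model, shifted).index
        rel = (after - before) / before if before > 0 else math.nan
        rows.append(
            {
                "subject_id": profile.subject_id,
                "before": before,
                "after": after,
                "relative_change": rel,
            }
        )
    if n_clamped:
        logger.warning("clamped %d shifted factor value(s) at %g", n_clamped, floor)
    per_subject = pd.DataFrame(
        rows, columns=["subject_id", "before", "after", "relative_change"]
    )
    n_excluded = int(per_subject["relative_change"].isna().sum()) if rows else 0
    if n_excluded:
        logger.info(
            "%d healthy subject(s) with before-index 0 excluded from the "
            "mean relative change",
            n_excluded,
        )
    valid = per_subject["relative_change"].dropna()
    mean_rel = float(valid.mean()) if len(valid) else math.nan
    mean_before = float(per_subject["before"].mean()) if rows else math.nan
    mean_after = float(per_subject["after"].mean()) if rows else math.nan
    rel_of_means = (
        (mean_after - mean_before) / mean_before
        if rows and mean_before > 0
        else math.nan
    )
    return InterventionSummary(
        per_subject=per_subject,
        mean_relative_change=mean_rel,
        relative_change_of_means=rel_of_means,
        n_subjects=len(rows),
        n_excluded_zero=n_excluded,
        deltas=dict(deltas),
    )


# ---------------------------------------------------------------------------
# Serialization

def model_to_dict(model: RiskModel) -> dict:
    return {
        "diseases": [
            {
                "name": d.name,
                "rules": [
                    {"factor": f.value, "threshold": th} for f, th in d.rules
                ],
            }
            for d in model.diseases
        ],
        "extrapolate_low": model.extrapolate_low,
        "healthy_ranges": {
            f.value: [lo, (None if math.isinf(hi) else hi)]
            for f, (lo, hi) in model.healthy_ranges.items()
        },
        "densities": [
            {"state_index": idx, "factor": f.value, **d.to_dict()}
            for (idx, f), d in sorted(
                model.densities.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
        ],
        "selection_report": list(model.selection_report),
    }


def model_from_dict(data: dict) -> RiskModel:
    diseases = tuple(load_disease_config(data["diseases"]))
    densities = {
        (int(entry["state_index"]), RiskFactor(entry["factor"])): FittedDensity.from_dict(entry)
        for entry in data["densities"]
    }
    healthy_ranges = {
        RiskFactor(name): (float(lo), math.inf if hi is None else float(hi))
        for name, (lo, hi) in data["healthy_ranges"].items()
    }
    return RiskModel(
        densities=densities,
        diseases=diseases,
        healthy_ranges=healthy_ranges,
        extrapolate_low=bool(data.get("extrapolate_low", False)),
        selection_report=tuple(data.get("selection_report", ())),
    )


def save_model(model: RiskModel, path: str | Path) -> None:
    """Serialize a model to JSON (exact float round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path: str | Path) -> RiskModel:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return model_from_dict(data)
    except (KeyError, ValueError) as exc:
        raise InputError(f"bad model JSON {path}: {exc}") from exc
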