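"""Seeded synthetic cohorts with the statistical structure the index assumes.

Real claims-derived cohorts of this kind are not redistributable, so the
generator stands in: it draws per-subject latent disease propensities, then
correlated, right-skewed factor vectors (log-normal marginals coupled by a
Gaussian copula) whose log-means shift upward with each active propensity.
State labels are *never* assigned directly — they are derived from the drawn
values through the same thresholding as real data, so labels and values are
consistent by construction.

Defaults emulate a mixed adult screening cohort: healthy medians well below
the clinical thresholds, log-scale spreads of 9–30%, a strong SBP–DBP
correlation and a moderate cholesterol–triglyceride correlation.  With 2000
subjects and a per-disease propensity of 0.3 all eight Triple H states are
populated well beyond the default minimum of 10 subjects.  The generator is
a statistical stand-in, not an epidemiological model: it does not reproduce
any real population's moments, age/sex structure, or measurement rounding
beyond 0.1-unit precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import (
    Cohort,
    DiseaseDefinition,
    RiskFactor,
    RiskFactorProfile,
    assign_state,
    state_space,
    triple_h_diseases,
)
from .errors import InputError, PreconditionError

__all__ = ["GeneratorConfig", "generate_cohort", "worked_example_deltas"]

_FACTORS = list(RiskFactor)

#: Median healthy value per factor (mg/dL, mg/dL, mg/dL, mmHg, mmHg).
DEFAULT_MEDIANS: dict[RiskFactor, float] = {
    RiskFactor.FPG: 90.0,
    RiskFactor.T_CHO: 165.0,
    RiskFactor.TG: 95.0,
    RiskFactor.SBP: 114.0,
    RiskFactor.DBP: 71.0,
}

#: Log-scale standard deviation per factor (right-skewed positive values).
DEFAULT_LOG_SD: dict[RiskFactor, float] = {
    RiskFactor.FPG: 0.12,
    RiskFactor.T_CHO: 0.12,
    RiskFactor.TG: 0.30,
    RiskFactor.SBP: 0.09,
    RiskFactor.DBP: 0.09,
}

#: Additive log-mean shift applied when the disease propensity is active.
DEFAULT_SHIFTS: dict[str, dict[RiskFactor, float]] = {
    "Hypertension": {RiskFactor.SBP: 0.30, RiskFactor.DBP: 0.30},
    "Hyperlipidemia": {RiskFactor.T_CHO: 0.35, RiskFactor.TG: 0.70},
    "Hyperglycemia": {RiskFactor.FPG: 0.50},
}

#: Gaussian-copula correlation across (FPG, T_CHO, TG, SBP, DBP).
DEFAULT_CORRELATION = (
    (1.00, 0.15, 0.20, 0.15, 0.10),
    (0.15, 1.00, 0.35, 0.10, 0.10),
    (0.20, 0.35, 1.00, 0.10, 0.10),
    (0.15, 0.10, 0.10, 1.00, 0.65),
    (0.10, 0.10, 0.10, 0.65, 1.00),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    ``disease_prevalence`` is the probability that a subject carries each
    disease's latent propensity (independently per disease);
    ``min_state_count`` is the smallest acceptable number of subjects per
    physiological state, enforced by redrawing the whole cohort up to
    ``max_retries`` times.
    """

    n_subjects: int = 2000
    seed: int = 0
    medians: Mapping[RiskFactor, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIANS)
    )
    log_sd: Mapping[RiskFactor, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_SD)
    )
    shifts: Mapping[str, Mapping[RiskFactor, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SHIFTS.items()}
    )
    correlation: tuple[tuple[float, ...], ...] = DEFAULT_CORRELATION
    disease_prevalence: float = 0.3
    min_state_count: int = 10
    max_retries: int = 25

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InputError("n_subjects must be positive")
        if not (0.0 <= self.disease_prevalence <= 1.0):
            raise InputError("disease_prevalence must be in [0, 1]")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(_FACTORS), len(_FACTORS)):
            raise InputError("correlation matrix must be 5x5")
        if not np.allclose(corr, corr.T):
            raise InputError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise InputError("correlation matrix must be positive definite")


def _draw(
    rng: np.random.Generator,
    config: GeneratorConfig,
    diseases: Sequence[DiseaseDefinition],
    chol: np.ndarray,
    start_id: int,
) -> list[RiskFactorProfile]:
    n = config.n_subjects
    propensity = rng.random((n, len(diseases))) < config.disease_prevalence
    z = rng.standard_normal((n, len(_FACTORS))) @ chol.T
    log_mu = np.log([config.medians[f] for f in _FACTORS])
    log_sd = np.array([config.log_sd[f] for f in _FACTORS])
    shift = np.zeros((n, len(_FACTORS)))
    for j, disease in enumerate(diseases):
        per_factor = config.shifts.get(disease.name, {})
        for i, factor in enumerate(_FACTORS):
            shift[:, i] += propensity[:, j] * float(per_factor.get(factor, 0.0))
    values = np.exp(log_mu[None, :] + shift + log_sd[None, :] * z)
    values = np.round(values, 1)  # clinical 0.1-unit measurement precision
    values = np.maximum(values, 0.1)
    return [
        RiskFactorProfile(
            str(start_id + i),
            {f: float(values[i, k]) for k, f in enumerate(_FACTORS)},
        )
        for i in range(n)
    ]


def generate_cohort(
    config: GeneratorConfig,
    diseases: Sequence[DiseaseDefinition] | None = None,
) -> Cohort:
    """Draw a cohort; deterministic for a given config (single seeded stream).

    Redraws the full cohort until every one of the ``2**n`` physiological
    states holds at least ``min_state_count`` subjects, or fails after
    ``max_retries`` attempts naming the deficient state.
    """
    diseases = list(diseases) if diseases is not None else triple_h_diseases()
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(np.asarray(config.correlation, dtype=float))
    states = state_space(diseases)
    worst_state, worst_count = None, -1
    for _attempt in range(max(config.max_retries, 1)):
        profiles = _draw(rng, config, diseases, chol, start_id=1)
        counts = {s: 0 for s in states}
        for p in profiles:
            counts[assign_state(p, diseases)] += 1
        short = [s for s in states if counts[s] < config.min_state_count]
        if not short:
            return Cohort(tuple(profiles))
        low = min(short, key=lambda s: counts[s])
        if worst_state is None or counts[low] > worst_count:
            worst_state, worst_count = low, counts[low]
    assert worst_state is not None
    raise PreconditionError(
        f"state {worst_state.label!r} reached only {worst_count} subjects "
        f"(< {config.min_state_count}) after {config.max_retries} redraws; "
        "increase n_subjects or the disease shifts"
    )


def worked_example_deltas() -> dict[RiskFactor, float]:
    """Mean six-week exercise-intervention reductions reported by Stewart
    et al. for the five factors (mg/dL and mmHg)."""
    return {
        RiskFactor.FPG: -0.2,
        RiskFactor.T_CHO: -5.2,
        RiskFactor.TG: -13.4,
        RiskFactor.SBP: -5.3,
        RiskFactor.DBP: -3.7,
    }
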