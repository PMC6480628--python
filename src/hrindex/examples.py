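"""A published ten-subject worked example for the health-risk index.

The original study scored ten subjects drawn from a 6496-subject Taiwanese
insurance cohort (not redistributable) against densities fitted to that
cohort.  The measured factor values, the per-factor component risks and the
resulting indices it printed are reproduced here as a fixture: the values
exercise every branch of the method (healthy subjects with graded indices,
subjects zeroed by a single threshold crossing, and a value sitting exactly
on a threshold).

Component risks and indices are as printed (4 decimal places).  Note the
component values themselves cannot be recomputed without the original
cohort; only their product structure and the threshold zero rule are
checkable.
"""

from __future__ import annotations

from .cohort import Cohort, RiskFactor, RiskFactorProfile

__all__ = [
    "worked_example_cohort",
    "worked_example_components",
    "worked_example_indices",
    "worked_example_states",
]

# subject_id: (FPG, T_CHO, TG, SBP, DBP), state label, components, index
_ROWS: dict[str, tuple] = {
    "1": ((89, 177, 153, 141, 90), "Hypertension",
          (0.9527, 0.4751, 0.2632, 0.0000, 0.0000), 0.0),
    "2": ((88, 185, 109, 124, 92), "Hypertension",
          (0.9579, 0.4100, 0.5070, 0.2521, 0.0000), 0.0),
    "3": ((86, 119, 56, 97, 60), "Normal",
          (0.9672, 0.8985, 1.0000, 0.9899, 0.8552), 0.7357),
    "4": ((238, 190, 103, 140, 69), "Hypertension & Hyperglycemia",
          (0.0000, 0.3606, 0.5591, 0.0000, 0.6752), 0.0),
    "5": ((80, 143, 53, 133, 67), "Normal",
          (0.9793, 0.7189, 1.0000, 0.0663, 0.7432), 0.0347),
    "6": ((105, 167, 99, 92, 60), "Normal",
          (0.3917, 0.5543, 0.6012, 0.9976, 0.8552), 0.1114),
    "7": ((79, 169, 117, 101, 73), "Normal",
          (0.9800, 0.5375, 0.4378, 0.9785, 0.4997), 0.1128),
    "8": ((97, 234, 263, 112, 80), "Hyperlipidemia",
          (0.8187, 0.0000, 0.0000, 0.7724, 0.3183), 0.0),
    "9": ((81, 167, 87, 109, 61), "Normal",
          (0.9785, 0.5543, 0.7346, 0.8627, 0.8512), 0.2926),
    "10": ((89, 152, 100, 110, 71), "Normal",
           (0.9527, 0.6766, 0.5901, 0.8425, 0.6256), 0.2005),
}

_FACTORS = list(RiskFactor)


def worked_example_cohort() -> Cohort:
    """The ten subjects' measured factor values, ids "1".."10"."""
    return Cohort(
        tuple(
            RiskFactorProfile(
                sid, {f: float(v) for f, v in zip(_FACTORS, row[0])}
            )
            for sid, row in _ROWS.items()
        )
    )


def worked_example_components() -> dict[str, tuple[float, ...]]:
    """Printed per-factor component risks (FPG, T_CHO, TG, SBP, DBP)."""
    return {sid: row[2] for sid, row in _ROWS.items()}


def worked_example_indices() -> dict[str, float]:
    """Printed health-risk indices."""
    return {sid: row[3] for sid, row in _ROWS.items()}


def worked_example_states() -> dict[str, str]:
    """Printed physiological state labels."""
    return {sid: row[1] for sid, row in _ROWS.items()}
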