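"""Per-factor risk ratio, multiplicative index, curves and interventions."""

import json
import math

import numpy as np
import pytest

from hrindex.cohort import (
    Cohort,
    DiseaseDefinition,
    RiskFactor,
    RiskFactorProfile,
    triple_h_diseases,
)
from hrindex.errors import InputError, PreconditionError
from hrindex.examples import (
    worked_example_cohort,
    worked_example_components,
    worked_example_indices,
)
from hrindex.kde import FittedDensity, Kernel, kernel_eval
from hrindex.risk import (
    RiskModel,
    build_risk_model,
    component_risk,
    health_risk_index,
    index_from_components,
    intervention_effect,
    model_from_dict,
    model_to_dict,
    risk_curve,
    score_cohort,
)
from hrindex.simulate import (
    DEFAULT_MEDIANS,
    GeneratorConfig,
    generate_cohort,
    worked_example_deltas,
)

F = RiskFactor


def uniform_density(center: float, value_at_center: float) -> FittedDensity:
    """A uniform-kernel KDE whose density at ``center`` equals the target."""
    h = 0.5 / value_at_center
    return FittedDensity((center, center), Kernel.UNIFORM, h)


def three_state_model(p1, p2, p3=None, *, t=100.0, lo=50.0, hi=140.0) -> RiskModel:
    """Hand-built single-factor model with prescribed densities at ``t``.

    Two diseases give a four-state space; densities are supplied for the
    healthy state and one or two disease states.
    """
    diseases = (
        DiseaseDefinition("Hypertension", ((F.SBP, hi),)),
        DiseaseDefinition("Hyperglycemia", ((F.FPG, 126.0),)),
    )
    densities = {
        (1, F.SBP): uniform_density(t, p1),
        (2, F.SBP): uniform_density(t, p2),
    }
    if p3 is not None:
        densities[(3, F.SBP)] = uniform_density(t, p3)
    return RiskModel(
        densities=densities,
        diseases=diseases,
        healthy_ranges={F.SBP: (lo, hi)},
    )


class TestComponentRisk:
    def test_hand_specified_three_state_ratio(self):
        """P1/(P1+P2+P3) with densities (0.6, 0.3, 0.1) at t is 0.6."""
        model = three_state_model(0.6, 0.3, 0.1)
        assert component_risk(model, F.SBP, 100.0) == pytest.approx(0.6, abs=1e-12)

    def test_only_healthy_density_positive_gives_one(self):
        diseases = (
            DiseaseDefinition("Hypertension", ((F.SBP, 140.0),)),
            DiseaseDefinition("Hyperglycemia", ((F.FPG, 126.0),)),
        )
        model = RiskModel(
            densities={
                (1, F.SBP): uniform_density(100.0, 0.5),
                (2, F.SBP): uniform_density(150.0, 0.5),  # support away from t
            },
            diseases=diseases,
            healthy_ranges={F.SBP: (50.0, 140.0)},
        )
        assert component_risk(model, F.SBP, 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_equal_densities_across_eight_states(self):
        disease_set = triple_h_diseases()
        densities = {
            (idx, F.SBP): uniform_density(100.0, 0.4) for idx in range(1, 9)
        }
        model = RiskModel(
            densities=densities,
            diseases=tuple(disease_set),
            healthy_ranges={F.SBP: (50.0, 140.0)},
        )
        assert component_risk(model, F.SBP, 100.0) == pytest.approx(0.125, abs=1e-12)

    def test_zero_at_and_above_threshold(self):
        model = three_state_model(0.6, 0.3, None)
        assert component_risk(model, F.SBP, 140.0) == 0.0
        assert component_risk(model, F.SBP, 155.0) == 0.0

    def test_strict_mode_zero_below_healthy_minimum(self):
        model = three_state_model(0.6, 0.3, None, lo=90.0)
        assert component_risk(model, F.SBP, 80.0) == 0.0

    def test_extrapolate_low_extends_ratio(self):
        disease = DiseaseDefinition("Hypertension", ((F.SBP, 140.0),))
        densities = {
            (1, F.SBP): FittedDensity((100.0, 110.0), Kernel.GAUSSIAN, 8.0),
            (2, F.SBP): FittedDensity((150.0, 160.0), Kernel.GAUSSIAN, 8.0),
        }
        strict = RiskModel(densities, (disease,), {F.SBP: (95.0, 140.0)})
        loose = RiskModel(
            densities, (disease,), {F.SBP: (95.0, 140.0)}, extrapolate_low=True
        )
        assert component_risk(strict, F.SBP, 90.0) == 0.0
        assert component_risk(loose, F.SBP, 90.0) > 0.9

    def test_zero_denominator_inside_range_gives_zero(self):
        model = three_state_model(0.6, 0.3, None)
        # uniform supports end well before 130
        assert component_risk(model, F.SBP, 130.0) == 0.0

    def test_bounded_between_zero_and_one(self, default_model):
        for factor in F:
            lo, hi = default_model.healthy_ranges[factor]
            grid = np.linspace(lo - 10, hi + 10, 301)
            vals = [component_risk(default_model, factor, t) for t in grid]
            assert all(0.0 <= v <= 1.0 for v in vals)


class TestHealthRiskIndex:
    @pytest.mark.parametrize("sid", ["3", "5", "6", "7", "9", "10"])
    def test_published_components_multiply_to_published_index(self, sid):
        comps = worked_example_components()[sid]
        assert round(index_from_components(comps), 4) == pytest.approx(
            worked_example_indices()[sid], abs=1e-12
        )

    def test_any_zero_component_zeroes_the_index(self):
        assert index_from_components((0.9, 0.0, 0.8, 0.7, 1.0)) == 0.0

    def test_index_equals_product_of_components(self, default_model):
        for p in worked_example_cohort():
            r = health_risk_index(default_model, p)
            prod = index_from_components([r.components[f] for f in F])
            assert r.index == pytest.approx(prod, abs=1e-6)

    def test_diseased_subjects_score_zero(self, default_model):
        for p in worked_example_cohort():
            r = health_risk_index(default_model, p)
            if not r.state.is_healthy:
                assert r.index == 0.0

    def test_zero_index_iff_some_zero_component(self, default_model, small_cohort):
        for p in small_cohort.profiles[:120]:
            r = health_risk_index(default_model, p)
            has_zero = any(r.components[f] == 0.0 for f in F)
            assert (r.index == 0.0) == has_zero

    def test_all_healthy_cohort_components_are_one(self):
        """With no diseased strata the ratio reduces to f1/f1 = 1."""
        low = {k: v * 0.6 for k, v in DEFAULT_MEDIANS.items()}
        cohort = generate_cohort(
            GeneratorConfig(
                n_subjects=300,
                seed=3,
                medians=low,
                disease_prevalence=0.0,
                min_state_count=0,
            )
        )
        model = build_risk_model(cohort)
        probe = RiskFactorProfile("m", {f: low[f] for f in F})
        r = health_risk_index(model, probe)
        assert r.index == pytest.approx(1.0, abs=1e-12)

    def test_empty_healthy_stratum_is_unrecoverable(self):
        sick = RiskFactorProfile(
            "s", {F.FPG: 200.0, F.T_CHO: 250.0, F.TG: 300.0, F.SBP: 160.0, F.DBP: 100.0}
        )
        sick2 = RiskFactorProfile(
            "s2", {F.FPG: 210.0, F.T_CHO: 255.0, F.TG: 310.0, F.SBP: 165.0, F.DBP: 105.0}
        )
        with pytest.raises(PreconditionError, match="healthy"):
            build_risk_model(Cohort((sick, sick2)))


class TestModelStructure:
    def test_full_grid_fitted_on_default_cohort(self, default_model):
        assert len(default_model.densities) == 8 * 5
        assert all(d.bandwidth > 0 for d in default_model.densities.values())
        assert len(default_model.selection_report) == 40

    def test_healthy_range_tops_are_the_minimal_thresholds(self, default_model):
        tops = {f: default_model.healthy_ranges[f][1] for f in F}
        assert tops == {
            F.FPG: 126.0,
            F.T_CHO: 200.0,
            F.TG: 200.0,
            F.SBP: 140.0,
            F.DBP: 90.0,
        }
        for f in F:
            lo, hi = default_model.healthy_ranges[f]
            assert lo <= hi

    def test_sparse_states_dropped_from_denominator(self):
        healthy = [
            RiskFactorProfile(
                f"h{i}",
                {F.FPG: 85.0 + i, F.T_CHO: 150.0 + i, F.TG: 90.0 + i,
                 F.SBP: 110.0 + i, F.DBP: 70.0 + i % 5},
            )
            for i in range(12)
        ]
        one_sick = RiskFactorProfile(
            "s", {F.FPG: 90.0, F.T_CHO: 150.0, F.TG: 95.0, F.SBP: 150.0, F.DBP: 95.0}
        )
        model = build_risk_model(Cohort(tuple(healthy + [one_sick])))
        assert all(idx == 1 for idx, _ in model.densities)


class TestSerialization:
    def test_round_trip_reproduces_risk_values(self, default_model):
        data = json.loads(json.dumps(model_to_dict(default_model)))
        back = model_from_dict(data)
        for factor in (F.SBP, F.FPG):
            lo, hi = default_model.healthy_ranges[factor]
            for t in np.linspace(lo, hi, 41):
                assert component_risk(back, factor, float(t)) == component_risk(
                    default_model, factor, float(t)
                )

    def test_brute_force_recomputation_from_serialized_densities(self, default_model):
        """Pure-Python recomputation of the ratio matches to 1e-10."""
        data = model_to_dict(default_model)
        by_factor: dict[str, list[dict]] = {}
        for entry in data["densities"]:
            by_factor.setdefault(entry["factor"], []).append(entry)
        for factor in F:
            lo, hi = default_model.healthy_ranges[factor]
            for t in np.linspace(lo, hi - 1e-9, 23):
                num = den = 0.0
                for entry in by_factor[factor.value]:
                    h = entry["bandwidth"]
                    total = 0.0
                    for xi in entry["samples"]:
                        total += float(kernel_eval(Kernel(entry["kernel"]), (t - xi) / h))
                    dens = total / (len(entry["samples"]) * h)
                    den += dens
                    if entry["state_index"] == 1:
                        num = dens
                expected = num / den if den > 0 else 0.0
                assert component_risk(default_model, factor, float(t)) == pytest.approx(
                    expected, abs=1e-10
                )


class TestRiskCurve:
    def test_grid_shape_and_alignment(self, default_model):
        rc = risk_curve(default_model, F.SBP)
        assert len(rc.grid) == len(rc.values) == 512
        assert all(b > a for a, b in zip(rc.grid, rc.grid[1:]))

    def test_values_clamped_to_unit_interval(self, default_model):
        rc = risk_curve(default_model, F.DBP)
        assert all(0.0 <= v <= 1.0 for v in rc.values)

    def test_zero_at_and_beyond_threshold(self, default_model):
        rc = risk_curve(default_model, F.SBP, lo=100.0, hi=160.0, points=121)
        for t, v in zip(rc.grid, rc.values):
            if t >= 140.0:
                assert v == 0.0

    def test_declines_toward_threshold_for_separated_disease(self):
        """With the diseased density far above the healthy one, the risk is
        non-increasing over the top decile of the healthy range."""
        disease = [DiseaseDefinition("Hypertension", ((F.SBP, 140.0),))]
        cohort = generate_cohort(
            GeneratorConfig(n_subjects=2000, seed=2, min_state_count=5), disease
        )
        model = build_risk_model(cohort, disease)
        lo, hi = model.healthy_ranges[F.SBP]
        rc = risk_curve(model, F.SBP, lo=hi - 0.1 * (hi - lo), hi=hi, points=40)
        diffs = np.diff(rc.values)
        assert np.all(diffs <= 1e-9)
        assert rc.values[-1] == 0.0

    def test_bad_grid_rejected(self, default_model):
        with pytest.raises(InputError):
            risk_curve(default_model, F.SBP, lo=150.0, hi=120.0)


class TestIntervention:
    def test_zero_deltas_change_nothing(self, default_model, small_cohort):
        summary = intervention_effect(
            default_model, small_cohort, {f: 0.0 for f in F}
        )
        assert summary.n_subjects > 0
        assert (summary.per_subject["after"] == summary.per_subject["before"]).all()
        valid = summary.per_subject["relative_change"].dropna()
        assert np.allclose(valid, 0.0)
        assert summary.mean_relative_change == pytest.approx(0.0)
        assert summary.relative_change_of_means == pytest.approx(0.0)

    def test_delta_crossing_threshold_zeroes_after_index(self, default_model):
        healthy = RiskFactorProfile(
            "h", {F.FPG: 90.0, F.T_CHO: 150.0, F.TG: 100.0, F.SBP: 120.0, F.DBP: 70.0}
        )
        summary = intervention_effect(
            default_model, Cohort((healthy,)), {F.SBP: 25.0}
        )
        assert summary.per_subject.loc[0, "after"] == 0.0

    def test_exercise_deltas_summary_structure(self, default_model, small_cohort):
        summary = intervention_effect(
            default_model, small_cohort, worked_example_deltas()
        )
        assert summary.n_subjects + 0 >= summary.n_excluded_zero >= 0
        assert math.isfinite(summary.relative_change_of_means)
        # both conventions are reported
        assert summary.mean_relative_change is not None
        assert set(summary.per_subject.columns) == {
            "subject_id", "before", "after", "relative_change"
        }

    def test_nonfinite_delta_rejected(self, default_model, small_cohort):
        with pytest.raises(InputError):
            intervention_effect(default_model, small_cohort, {F.SBP: math.inf})

    def test_huge_negative_delta_is_clamped(self, default_model):
        healthy = RiskFactorProfile(
            "h", {F.FPG: 90.0, F.T_CHO: 150.0, F.TG: 100.0, F.SBP: 120.0, F.DBP: 70.0}
        )
        summary = intervention_effect(
            default_model, Cohort((healthy,)), {F.TG: -1e9}
        )
        assert len(summary.per_subject) == 1  # runs, values floored


class TestScoreCohort:
    def test_layout_mirrors_published_table(self, default_model):
        table = score_cohort(default_model, worked_example_cohort())
        assert list(table.columns) == (
            ["subject_id"] + [f.value for f in F] + ["state", "index"]
        )
        assert len(table) == 10
        zeroed = table[table["subject_id"].isin(["1", "2", "4", "8"])]
        assert (zeroed["index"] == 0.0).all()

    def test_score_invariant_to_row_order(self, default_model):
        cohort = worked_example_cohort()
        reversed_cohort = Cohort(tuple(reversed(cohort.profiles)))
        a = score_cohort(default_model, cohort).set_index("subject_id")
        b = score_cohort(default_model, reversed_cohort).set_index("subject_id")
        assert a.sort_index().equals(b.sort_index())
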