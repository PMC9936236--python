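"""Objective function: gEUD, one-sided costs, the hybrid total, the optimizer."""

import numpy as np
import pytest
from scipy import sparse

from moapn.dose_engine import InfluenceMatrix
from moapn.phantom import RING_NAMES
from moapn.plan_optim import (
    ObjectiveEntry,
    ObjectiveSet,
    OptimConfig,
    cost_geud,
    cost_point,
    geud,
    optimize_plan,
    total_objective,
)


class TestGeud:
    @pytest.mark.parametrize("a", [-5.0, 1.0, 3.0, 40.0])
    def test_uniform_dose_is_fixed_point(self, a):
        assert geud(np.full(37, 12.5), a) == pytest.approx(12.5, rel=1e-12)

    def test_a_equal_one_is_exact_mean(self):
        assert geud(np.array([0.0, 10.0, 20.0]), 1.0) == 10.0

    def test_a40_matches_arbitrary_precision_oracle(self):
        import sympy

        d = [10, 20]
        expected = float(
            sympy.N((sympy.Rational(1, 2) * (10**40 + 20**40)) ** sympy.Rational(1, 40), 30)
        )
        assert geud(np.array(d, float), 40.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_a_and_bounded_by_max(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = rng.uniform(0.1, 60.0, size=rng.integers(2, 40))
            values = [geud(d, a) for a in (0.5, 1.0, 2.0, 10.0, 40.0)]
            assert all(v1 <= v2 + 1e-9 for v1, v2 in zip(values, values[1:]))
            assert values[-1] <= d.max() + 1e-9
            assert geud(d, 1.0) == pytest.approx(d.mean(), rel=1e-12)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="empty"):
            geud(np.array([]), 1.0)
        with pytest.raises(ValueError, match="negative a"):
            geud(np.array([0.0, 5.0]), -2.0)
        with pytest.raises(ValueError, match="non-zero"):
            geud(np.array([1.0]), 0.0)


class TestPointCost:
    def test_satisfied_upper_and_lower_cost_zero(self):
        up = ObjectiveEntry("PTV", "point_upper", 50.0, 300.0)
        lo = ObjectiveEntry("PTV", "point_lower", 50.0, 300.0)
        d = np.full(10, 50.0)
        assert cost_point(d - 1.0, up) == 0.0
        assert cost_point(d + 1.0, lo) == 0.0

    def test_single_voxel_upper_violation(self):
        # (1/2) * 300 * (52 - 50)^2 = 600
        e = ObjectiveEntry("PTV", "point_upper", 50.0, 300.0)
        assert cost_point(np.array([52.0]), e) == pytest.approx(600.0)

    def test_empty_structure_errors(self):
        e = ObjectiveEntry("PTV", "point_upper", 50.0, 300.0)
        with pytest.raises(ValueError, match="empty"):
            cost_point(np.array([]), e)


class TestGeudCost:
    def test_met_objective_costs_zero_and_continuity(self):
        e = ObjectiveEntry("Ring1", "geud_upper", 15.0, 150.0, a_param=40.0)
        assert cost_geud(np.full(5, 10.0), e) == 0.0
        # approach the threshold from above: cost -> 0 continuously
        assert cost_geud(np.full(5, 15.0 + 1e-8), e) < 1e-10

    def test_exceeded_objective_square_law(self):
        # w (gEUD - D_EUD)^2 = 150 * (16 - 15)^2 = 150
        e = ObjectiveEntry("Ring1", "geud_upper", 15.0, 150.0, a_param=40.0)
        assert cost_geud(np.full(8, 16.0), e) == pytest.approx(150.0, rel=1e-9)


class TestTotalObjective:
    def test_zero_dose_activates_only_ptv_lower(self, small_case, small_objectives):
        dose = np.zeros(small_case.grid.shape)
        total = total_objective(dose, small_case, small_objectives)
        lower = small_objectives.entry_for("PTV", "point_lower")
        expected = cost_point(dose[small_case.mask("PTV")], lower)
        assert total == pytest.approx(expected)
        assert total > 0

    def test_fully_satisfied_plan_costs_zero(self, small_case, small_objectives):
        # uniform dose between the PTV window inside PTV, zero elsewhere is
        # unphysical but exercises the objective algebra directly
        objectives = small_objectives.copy()
        dose = np.zeros(small_case.grid.shape)
        dose[small_case.mask("PTV")] = objectives.entry_for("PTV", "point_lower").dose_gy
        assert total_objective(dose, small_case, objectives) == 0.0

    def test_equals_sum_of_independent_terms(self, small_case, small_objectives):
        rng = np.random.default_rng(5)
        dose = rng.uniform(0, 60, small_case.grid.shape)
        total = total_objective(dose, small_case, small_objectives)
        acc = 0.0
        for e in small_objectives.entries:
            d = dose[small_case.mask(e.structure)]
            acc += cost_geud(d, e) if e.kind == "geud_upper" else cost_point(d, e)
        assert total == pytest.approx(acc, rel=1e-12)

    def test_invariant_to_voxel_ordering(self):
        e = ObjectiveEntry("Ring1", "geud_upper", 10.0, 150.0, a_param=40.0)
        d = np.array([5.0, 20.0, 11.0, 3.0])
        assert cost_geud(d, e) == pytest.approx(cost_geud(d[::-1], e))


class TestObjectiveSet:
    def test_requires_exactly_one_ptv_window(self):
        with pytest.raises(ValueError, match="point_lower"):
            ObjectiveSet(entries=[ObjectiveEntry("PTV", "point_upper", 67.5, 300.0)])

    def test_non_ptv_point_objective_rejected(self):
        entries = [
            ObjectiveEntry("PTV", "point_lower", 52.0, 300.0),
            ObjectiveEntry("PTV", "point_upper", 67.5, 300.0),
            ObjectiveEntry("Ring1", "point_upper", 40.0, 150.0),
        ]
        with pytest.raises(ValueError, match="geud_upper"):
            ObjectiveSet(entries=entries)

    def test_json_round_trip(self, small_objectives, tmp_path):
        path = tmp_path / "objs.json"
        small_objectives.to_json(path)
        loaded = ObjectiveSet.from_json(path)
        assert loaded.prescription_gy == small_objectives.prescription_gy
        for a, b in zip(small_objectives.entries, loaded.entries):
            assert (a.structure, a.kind, a.dose_gy, a.weight, a.a_param) == (
                b.structure, b.kind, b.dose_gy, b.weight, b.a_param,
            )


def _toy_problem(influence_value=2.0):
    """One beamlet, one PTV voxel: closed-form optimum w* = D_obj / a."""
    from moapn.phantom import Case, GridSpec

    grid = GridSpec((16, 16, 16), (5.0, 5.0, 5.0))
    masks = {
        "PTV": np.zeros(grid.shape, bool),
        "body": np.ones(grid.shape, bool),
    }
    masks["PTV"][8, 8, 8] = True
    case = Case(grid=grid, masks=masks, seed=0)
    flat = np.flatnonzero(masks["body"].ravel())
    row = int(np.flatnonzero(masks["PTV"].ravel()[flat])[0])
    entries = sparse.csr_matrix(
        ([influence_value], ([row], [0])), shape=(flat.size, 1)
    )
    infl = InfluenceMatrix(
        entries=entries,
        voxel_index=flat,
        beamlet_angle_deg=np.zeros(1),
        beamlet_offset_u_mm=np.zeros(1),
        beamlet_offset_v_mm=np.zeros(1),
        grid_shape=grid.shape,
    )
    objectives = ObjectiveSet(
        entries=[
            ObjectiveEntry("PTV", "point_lower", 52.0, 300.0),
            ObjectiveEntry("PTV", "point_upper", 67.5, 300.0),
        ]
    )
    return case, infl, objectives


class TestOptimizePlan:
    def test_toy_problem_reaches_closed_form_optimum(self):
        case, infl, objectives = _toy_problem(2.0)
        plan = optimize_plan(infl, case, objectives)
        assert plan.weights[0] * 2.0 == pytest.approx(52.0, rel=0.01)
        assert plan.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_objective_trace_non_increasing(self, small_case, small_influence,
                                            small_objectives):
        plan = optimize_plan(small_influence, small_case, small_objectives,
                             OptimConfig(maxiter=60))
        trace = np.asarray(plan.objective_trace)
        assert (np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1.0)).all()

    def test_warm_start_never_worsens(self, small_case, small_influence,
                                      small_objectives, small_plan):
        again = optimize_plan(
            small_influence, small_case, small_objectives,
            warm_start=small_plan.weights,
        )
        assert again.objective_value <= small_plan.objective_value + 1e-9

    @pytest.mark.parametrize("ring", RING_NAMES)
    def test_tightening_one_ring_does_not_raise_its_geud(
        self, small_case, small_influence, small_objectives, ring
    ):
        """Extra pressure on a single ring's objective never increases that
        ring's converged gEUD (tightening several rings at once may instead
        redistribute dose between them)."""
        base = optimize_plan(small_influence, small_case, small_objectives)
        tightened = small_objectives.copy()
        tightened.entry_for(ring, "geud_upper").dose_gy *= 0.9
        pressed = optimize_plan(
            small_influence, small_case, tightened, warm_start=base.weights
        )
        assert pressed.ring_geud[ring] <= base.ring_geud[ring] + 0.05
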