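"""Unit tests for the range directional model: ranges, scores, slacks, references."""

import numpy as np
import pytest

from medeff import (
    ContractError,
    Panel,
    Role,
    SolverStatus,
    UnitProfile,
    UnknownUnitError,
    ValidationError,
    Variable,
    VariableSchema,
    compute_ranges,
    compute_slacks,
    evaluate_all,
    random_panel,
    reference_weights,
    solve_rdm,
)

from conftest import make_panel


class TestComputeRanges:
    def test_input_range_is_distance_to_panel_minimum(self, xy_schema):
        p = make_panel(
            xy_schema,
            {"A": {"x": 1, "y": 1}, "B": {"x": 2, "y": 1}, "C": {"x": 3, "y": 1}},
        )
        assert compute_ranges(p, "B").input_ranges["x"] == pytest.approx(1.0)

    def test_desirable_range_zero_at_panel_maximum(self, xy_schema):
        p = make_panel(xy_schema, {"A": {"x": 1, "y": 2}, "B": {"x": 1, "y": 4}})
        assert compute_ranges(p, "B").desirable_ranges["y"] == 0.0
        assert compute_ranges(p, "A").desirable_ranges["y"] == pytest.approx(2.0)

    def test_undesirable_range_uses_input_like_formula(self, xyz_schema):
        p = make_panel(
            xyz_schema,
            {
                "A": {"x": 1, "y": 1, "z": 0.8},
                "B": {"x": 1, "y": 1, "z": 1.2},
            },
        )
        assert compute_ranges(p, "B").undesirable_ranges["z"] == pytest.approx(0.4)
        assert compute_ranges(p, "A").undesirable_ranges["z"] == 0.0

    def test_unknown_unit_raises(self, three_unit_panel):
        with pytest.raises(UnknownUnitError):
            compute_ranges(three_unit_panel, "nope")

    def test_absent_role_gives_empty_mapping(self, three_unit_panel):
        assert compute_ranges(three_unit_panel, "A").undesirable_ranges == {}


class TestSolveRdm:
    def test_hand_solved_three_unit_fixture(self, three_unit_panel):
        res = solve_rdm(three_unit_panel, "C")
        assert res.theta_star == pytest.approx(0.5, abs=1e-9)
        assert res.efficiency == pytest.approx(0.5, abs=1e-9)
        assert res.lambdas["A"] == pytest.approx(0.5, abs=1e-7)
        assert res.lambdas["B"] == pytest.approx(0.5, abs=1e-7)
        assert set(res.reference_set) == {"A", "B"}
        assert res.solver_status is SolverStatus.OPTIMAL

    def test_all_extremes_unit_is_efficient_by_convention(self, xy_schema):
        p = make_panel(
            xy_schema, {"best": {"x": 1, "y": 9}, "other": {"x": 2, "y": 3}}
        )
        res = solve_rdm(p, "best")
        assert res.theta_star == 0.0
        assert res.efficiency == 1.0
        assert res.reference_set == ("best",)

    def test_negative_desirable_output_worst_case_theta_one(self, xy_schema):
        # R_y = 10; lambda_A = 1 gives 5 - 10*theta >= -5 so theta <= 1
        p = make_panel(xy_schema, {"A": {"x": 1, "y": 5}, "B": {"x": 1, "y": -5}})
        res = solve_rdm(p, "B")
        assert res.theta_star == pytest.approx(1.0, abs=1e-9)
        assert res.efficiency == pytest.approx(0.0, abs=1e-9)

    def test_undesirable_output_worst_case_theta_one(self, xyz_schema):
        p = make_panel(
            xyz_schema,
            {
                "A": {"x": 1, "y": 1, "z": 0.8},
                "B": {"x": 1, "y": 1, "z": 1.2},
            },
        )
        assert solve_rdm(p, "B").theta_star == pytest.approx(1.0, abs=1e-9)

    def test_weights_sum_to_one_and_nonnegative(self, rng):
        p = random_panel(rng, 12, 1, 2, 1)
        for res in evaluate_all(p):
            lam = np.array(list(res.lambdas.values()))
            assert lam.min() >= 0.0
            assert lam.sum() == pytest.approx(1.0, abs=1e-7)


class TestEvaluateAll:
    def test_three_unit_fixture_efficiencies(self, three_unit_panel):
        eff = {r.unit_id: r.efficiency for r in evaluate_all(three_unit_panel)}
        assert eff == pytest.approx({"A": 1.0, "B": 1.0, "C": 0.5}, abs=1e-9)

    def test_identical_units_all_efficient(self, xy_schema):
        p = make_panel(
            xy_schema, {f"u{i}": {"x": 1.5, "y": 0.7} for i in range(5)}
        )
        assert all(r.theta_star == 0.0 for r in evaluate_all(p))

    def test_results_in_panel_order_and_deterministic(self, rng):
        p = random_panel(rng, 20, 1, 2, 1)
        first = evaluate_all(p)
        second = evaluate_all(p)
        assert [r.unit_id for r in first] == list(p.ids)
        assert [r.theta_star for r in first] == [r.theta_star for r in second]

    def test_large_random_panel_bounded(self, rng):
        p = random_panel(rng, 200, 1, 2, 1)
        for r in evaluate_all(p):
            assert 0.0 <= r.theta_star <= 1.0
            assert 0.0 <= r.efficiency <= 1.0


class TestComputeSlacks:
    def test_strongly_efficient_unit_has_no_slack(self, xy_schema):
        p = make_panel(xy_schema, {"best": {"x": 1, "y": 9}, "o": {"x": 2, "y": 3}})
        res = solve_rdm(p, "best")
        rep = compute_slacks(p, "best", res)
        assert all(v == 0.0 for v in rep.raw_slack.values())
        assert rep.largest_slack_variable is None

    def test_projection_onto_facet_leaves_zero_slack(self, three_unit_panel):
        res = solve_rdm(three_unit_panel, "C")
        rep = compute_slacks(three_unit_panel, "C", res)
        assert rep.raw_slack["x"] == pytest.approx(0.0, abs=1e-7)
        assert rep.raw_slack["y"] == pytest.approx(0.0, abs=1e-7)

    def test_weakly_dominated_unit_projects_onto_facet(self, xy_schema):
        # D is dominated, but its range direction still meets the strong
        # frontier: theta* = 2/3 with both constraints binding, so no slack.
        p = make_panel(
            xy_schema,
            {"A": {"x": 1, "y": 2}, "B": {"x": 2, "y": 4}, "D": {"x": 3, "y": 2}},
        )
        res = solve_rdm(p, "D")
        assert res.theta_star == pytest.approx(2 / 3, abs=1e-9)
        rep = compute_slacks(p, "D", res)
        assert max(rep.raw_slack.values()) == pytest.approx(0.0, abs=1e-7)

    def test_nonbinding_input_constraint_yields_positive_slack(self):
        # With two inputs the second input cannot absorb theta fully:
        # at theta*=1/2 the x2 envelopment constraint keeps a residual of 1.
        schema = VariableSchema(
            [
                Variable("x1", Role.INPUT),
                Variable("x2", Role.INPUT),
                Variable("y", Role.DESIRABLE),
            ]
        )
        p = make_panel(
            schema,
            {
                "P": {"x1": 1, "x2": 1, "y": 2},
                "Q": {"x1": 2, "x2": 2, "y": 4},
                "T": {"x1": 2, "x2": 4, "y": 2},
            },
        )
        res = solve_rdm(p, "T")
        assert res.theta_star == pytest.approx(0.5, abs=1e-9)
        rep = compute_slacks(p, "T", res)
        assert rep.raw_slack["x2"] == pytest.approx(1.0, abs=1e-7)
        assert rep.normalized_slack["x2"] == pytest.approx(1 / 3, abs=1e-7)
        assert rep.largest_slack_variable == "x2"

    def test_slack_projection_matches_reference_combination(self, rng):
        # projected point (inputs minus theta*R minus slack, outputs plus
        # theta*R plus slack) must equal the phase-II lambda-combination
        p = random_panel(rng, 10, 2, 2, 1)
        for uid in p.ids:
            res = solve_rdm(p, uid)
            rep = compute_slacks(p, uid, res)
            ranges = compute_ranges(p, uid)
            lam = np.array([rep.lambdas[u] for u in p.ids])
            i = p.index_of(uid)
            assert lam.sum() == pytest.approx(1.0, abs=1e-7)
            for role in (Role.INPUT, Role.DESIRABLE, Role.UNDESIRABLE):
                mat = p.matrix(role)
                for j, name in enumerate(p.schema.names(role)):
                    combo = float(lam @ mat[:, j])
                    r = ranges.of(name)
                    if role is Role.DESIRABLE:
                        projected = mat[i, j] + res.theta_star * r + rep.raw_slack[name]
                    else:
                        projected = mat[i, j] - res.theta_star * r - rep.raw_slack[name]
                    assert combo == pytest.approx(projected, abs=1e-6)

    def test_mismatched_result_rejected(self, three_unit_panel):
        res = solve_rdm(three_unit_panel, "C")
        with pytest.raises(ContractError):
            compute_slacks(three_unit_panel, "A", res)


class TestReferenceWeights:
    def test_three_unit_fixture_decomposition(self, three_unit_panel):
        res = solve_rdm(three_unit_panel, "C")
        refs = reference_weights(res, 0.01)
        assert refs == pytest.approx({"A": 0.5, "B": 0.5}, abs=1e-7)
        assert sum(refs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_efficient_unit_references_itself(self, three_unit_panel):
        res = solve_rdm(three_unit_panel, "A")
        assert reference_weights(res, 0.01) == pytest.approx({"A": 1.0})

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.5, 2.0])
    def test_threshold_must_be_in_open_unit_interval(self, three_unit_panel, threshold):
        res = solve_rdm(three_unit_panel, "C")
        with pytest.raises(ValidationError):
            reference_weights(res, threshold)

    def test_never_empty_below_one_over_n(self, rng):
        p = random_panel(rng, 8, 1, 2, 0)
        for uid in p.ids:
            refs = reference_weights(solve_rdm(p, uid), threshold=1 / 10)
            assert refs
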