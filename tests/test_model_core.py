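"""Unit tests for curve construction, shifting and the delivered-volume rule."""

import math

import pytest

from mhcapsim import (
    BindingSide,
    CurveRole,
    LinearCurve,
    ParameterSet,
    PriceQuantitySchedule,
    build_demand_schedule,
    build_supply_schedule,
    curve_intersection,
    delivered_volume,
    fit_linear_curve,
    round_services,
    shift_demand_additive,
    shift_supply_proportional,
)
from mhcapsim.model_core import (
    CollinearityError,
    DomainError,
    ParallelCurvesError,
    RoleError,
)


class TestRoundServices:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (84.5, 85),  # tie away from zero, not banker's 84
            (71.5, 72),
            (78.0, 78),
            (-2.5, -3),
            (0.49999999, 0),
            (60 * 1.3, 78),  # binary representation noise must not flip the result
            (65 * 1.3, 85),
            (55 * 1.3, 72),
        ],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_services(x) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(DomainError):
            round_services(bad)


class TestScheduleConstruction:
    def test_demand_matches_reference_grid(self, base_params, base_grid):
        sched = build_demand_schedule(base_params, base_grid)
        assert sched.role is CurveRole.DEMAND
        assert sched.quantities == (100.0, 80.0, 60.0, 40.0, 20.0)

    def test_supply_matches_reference_grid(self, base_params, base_grid):
        sched = build_supply_schedule(base_params, base_grid)
        assert sched.role is CurveRole.SUPPLY
        assert sched.quantities == (20.0, 40.0, 60.0, 80.0, 100.0)

    @pytest.mark.parametrize("builder", [build_demand_schedule, build_supply_schedule])
    def test_single_point_passthrough(self, builder, base_params):
        sched = builder(base_params, [150.0])
        assert sched.points == ((150.0, 60.0),)

    @pytest.mark.parametrize(
        "builder,q0",
        [(build_demand_schedule, 55.0), (build_supply_schedule, 65.0)],
    )
    def test_anchored_through_reference_point(self, builder, q0, base_grid):
        params = ParameterSet(q0=q0, q0_bounds=(50.0, 70.0))
        sched = builder(params, base_grid)
        assert dict(sched.points)[150.0] == pytest.approx(q0)

    @pytest.mark.parametrize("grid", [[], [0.0, 100.0], [-50.0]])
    def test_bad_grid_rejected(self, base_params, grid):
        with pytest.raises(ValueError):
            build_demand_schedule(base_params, grid)

    def test_negative_quantity_names_offending_point(self, base_params):
        with pytest.raises(DomainError, match="400"):
            build_demand_schedule(base_params, [150.0, 400.0])

    def test_points_normalized_ascending(self):
        sched = PriceQuantitySchedule(
            role=CurveRole.DEMAND, points=((250.0, 20.0), (50.0, 100.0), (150.0, 60.0))
        )
        assert sched.prices == (50.0, 150.0, 250.0)

    def test_monotonicity_enforced_per_role(self):
        with pytest.raises(ValueError, match="non-increasing"):
            PriceQuantitySchedule(role=CurveRole.DEMAND, points=((50.0, 10.0), (100.0, 20.0)))
        with pytest.raises(ValueError, match="non-decreasing"):
            PriceQuantitySchedule(role=CurveRole.SUPPLY, points=((50.0, 20.0), (100.0, 10.0)))

    def test_duplicate_proxies_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PriceQuantitySchedule(role=CurveRole.SUPPLY, points=((50.0, 1.0), (50.0, 2.0)))


class TestShifts:
    def test_additive_demand_shift_reproduces_post_column(self, base_params, base_grid):
        pre = build_demand_schedule(base_params, base_grid)
        post = shift_demand_additive(pre, 27.0)
        assert post.quantities == (127.0, 107.0, 87.0, 67.0, 47.0)
        assert all(q_post - q_pre == 27.0 for q_pre, q_post in zip(pre.quantities, post.quantities))

    def test_proportional_supply_shift_reproduces_post_column(self, base_params, base_grid):
        pre = build_supply_schedule(base_params, base_grid)
        post = shift_supply_proportional(pre, 0.30)
        assert post.quantities == (26.0, 52.0, 78.0, 104.0, 130.0)

    def test_zero_shift_is_identity(self, base_params, base_grid):
        demand = build_demand_schedule(base_params, base_grid)
        supply = build_supply_schedule(base_params, base_grid)
        assert shift_demand_additive(demand, 0.0).quantities == demand.quantities
        assert shift_supply_proportional(supply, 0.0).quantities == supply.quantities

    def test_single_point_shifts(self):
        demand = PriceQuantitySchedule(role=CurveRole.DEMAND, points=((150.0, 60.0),))
        assert shift_demand_additive(demand, 35.0).points == ((150.0, 95.0),)
        supply = PriceQuantitySchedule(role=CurveRole.SUPPLY, points=((150.0, 55.0),))
        # 55 * 1.3 = 71.5 rounds away from zero to 72
        assert shift_supply_proportional(supply, 0.30).points == ((150.0, 72.0),)

    def test_role_mismatch_is_usage_error(self, base_params, base_grid):
        demand = build_demand_schedule(base_params, base_grid)
        supply = build_supply_schedule(base_params, base_grid)
        with pytest.raises(RoleError):
            shift_demand_additive(supply, 10.0)
        with pytest.raises(RoleError):
            shift_supply_proportional(demand, 0.1)

    def test_full_contraction_rejected(self, base_params, base_grid):
        supply = build_supply_schedule(base_params, base_grid)
        with pytest.raises(DomainError):
            shift_supply_proportional(supply, -1.0)


class TestDeliveredVolume:
    @pytest.mark.parametrize(
        "q0,dd,dc,delivered,unmet,binding",
        [
            (60, 27, 0.30, 78, 9, BindingSide.CAPACITY_LIMITED),  # headline case
            (60, 0, 0, 60, 0, BindingSide.BALANCED),
            (65, 27, 0.30, 85, 7, BindingSide.CAPACITY_LIMITED),  # 84.5 rounds up
            (55, 27, 0.30, 72, 10, BindingSide.CAPACITY_LIMITED),  # 71.5 rounds up
            (60, 20, 0.40, 80, 0, BindingSide.DEMAND_LIMITED),
            (60, 35, 0.20, 72, 23, BindingSide.CAPACITY_LIMITED),
        ],
    )
    def test_min_rule(self, q0, dd, dc, delivered, unmet, binding):
        res = delivered_volume(q0, dd, dc)
        assert res.delivered == delivered
        assert res.unmet == unmet
        assert res.binding is binding

    def test_headline_demand_implied(self):
        res = delivered_volume(60, 27, 0.30)
        assert res.demand_implied == 87
        assert res.capacity_implied == pytest.approx(78)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            delivered_volume(0, 27, 0.30)


class TestCurveFitAndIntersection:
    def test_fit_reference_demand_column(self, base_params, base_grid):
        curve = fit_linear_curve(build_demand_schedule(base_params, base_grid))
        assert curve.intercept == pytest.approx(120.0, abs=1e-9)
        assert curve.slope == pytest.approx(-0.4, abs=1e-12)

    def test_fit_reference_supply_column(self, base_params, base_grid):
        curve = fit_linear_curve(build_supply_schedule(base_params, base_grid))
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.slope == pytest.approx(0.4, abs=1e-12)

    def test_flat_supply_accepted(self):
        sched = PriceQuantitySchedule(role=CurveRole.SUPPLY, points=((50.0, 30.0), (100.0, 30.0)))
        assert fit_linear_curve(sched).slope == 0.0

    def test_non_collinear_reports_residual(self):
        sched = PriceQuantitySchedule(
            role=CurveRole.SUPPLY, points=((50.0, 10.0), (100.0, 30.0), (150.0, 40.0))
        )
        with pytest.raises(CollinearityError, match="residual"):
            fit_linear_curve(sched)

    def test_single_point_cannot_be_fitted(self):
        sched = PriceQuantitySchedule(role=CurveRole.DEMAND, points=((150.0, 60.0),))
        with pytest.raises(ValueError, match="two points"):
            fit_linear_curve(sched)

    def test_slope_sign_role_conflict_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            LinearCurve(role=CurveRole.DEMAND, intercept=0.0, slope=0.4)

    def test_baseline_intersection(self, base_params, base_grid):
        d = fit_linear_curve(build_demand_schedule(base_params, base_grid))
        s = fit_linear_curve(build_supply_schedule(base_params, base_grid))
        pt = curve_intersection(d, s)
        assert pt.price_proxy == pytest.approx(150.0, abs=1e-9)
        assert pt.quantity == pytest.approx(60.0, abs=1e-9)
        assert pt.feasible

    def test_post_shift_intersection_by_hand(self):
        # 147 - 0.4 p = 0.52 p  =>  p = 147/0.92
        d = LinearCurve(role=CurveRole.DEMAND, intercept=147.0, slope=-0.4)
        s = LinearCurve(role=CurveRole.SUPPLY, intercept=0.0, slope=0.52)
        pt = curve_intersection(d, s)
        assert pt.price_proxy == pytest.approx(147.0 / 0.92)
        assert pt.quantity == pytest.approx(0.52 * 147.0 / 0.92)
        assert pt.quantity == pytest.approx(83.087, abs=1e-3)

    def test_parallel_curves_rejected(self):
        flat_d = LinearCurve(role=CurveRole.DEMAND, intercept=80.0, slope=0.0)
        flat_s = LinearCurve(role=CurveRole.SUPPLY, intercept=20.0, slope=0.0)
        with pytest.raises(ParallelCurvesError):
            curve_intersection(flat_d, flat_s)

    def test_infeasible_intersection_flagged_not_hidden(self):
        d = LinearCurve(role=CurveRole.DEMAND, intercept=10.0, slope=-0.4)
        s = LinearCurve(role=CurveRole.SUPPLY, intercept=50.0, slope=0.4)
        pt = curve_intersection(d, s)
        assert pt.price_proxy < 0
        assert not pt.feasible


class TestParameterSet:
    def test_zero_copayment_enforced(self):
        with pytest.raises(ValueError, match="zero-copayment"):
            ParameterSet(user_copay=5.0)

    def test_bounds_must_bracket_base(self):
        with pytest.raises(ValueError, match="delta_d"):
            ParameterSet(delta_d=50.0)

    def test_contraction_needs_explicit_flag(self):
        with pytest.raises(ValueError, match="contraction"):
            ParameterSet(delta_d=-5.0, delta_d_bounds=(-10.0, 0.0))
        p = ParameterSet(delta_d=-5.0, delta_d_bounds=(-10.0, 0.0), allow_contraction=True)
        assert p.delta_d == -5.0

    def test_frozen(self, base_params):
        with pytest.raises(Exception):
            base_params.q0 = 70.0
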