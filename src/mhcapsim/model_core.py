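"""Core supply-demand mechanics for a capacity-constrained service system.

The model represents a publicly funded mental-health system in which the
user-facing price is zero by policy design, so utilization is governed by
capacity and help-seeking rather than price.  Curves are expressed over a
*unit-cost proxy* (CAD/service) that exists purely to visualize equilibrium
mechanics; it is not an observed market price and not a patient copayment.

Three parameters drive the model:

* ``q0`` -- baseline equilibrium quantity (services/month),
* ``delta_d`` -- an additive rightward demand shift (services/month),
* ``delta_c`` -- a proportional capacity (supply) expansion (fraction).

The delivered volume is the capacity-constrained minimum::

    Q* = min(Q0 + delta_d, Q0 * (1 + delta_c))

rounded to whole services (ties away from zero).  The gap between the
demand-implied volume and Q* is unmet demand, interpreted as congestion or
queueing pressure rather than additional utilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence, Tuple

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "BindingSide",
    "CurveRole",
    "DomainError",
    "CollinearityError",
    "ParallelCurvesError",
    "RoleError",
    "ParameterSet",
    "PriceQuantitySchedule",
    "LinearCurve",
    "EquilibriumResult",
    "IntersectionPoint",
    "DEFAULT_DEMAND_SLOPE",
    "DEFAULT_SUPPLY_SLOPE",
    "round_services",
    "build_demand_schedule",
    "build_supply_schedule",
    "shift_demand_additive",
    "shift_supply_proportional",
    "delivered_volume",
    "classify_binding",
    "fit_linear_curve",
    "curve_intersection",
]

#: Default curve slopes (services/month per CAD/service), implied by the
#: equally spaced reference grids: quantity changes by 20 services/month per
#: 50 CAD/service step.  Stored as module defaults rather than hard-coded in
#: the construction routines so a config can override them.
DEFAULT_DEMAND_SLOPE = -0.4
DEFAULT_SUPPLY_SLOPE = 0.4

#: Absolute tolerance used for "balanced" classification and collinearity.
TOL = 1e-9


class DomainError(ValueError):
    """A value is outside the model's meaningful domain."""


class RoleError(TypeError):
    """A schedule with the wrong role (demand vs supply) was supplied."""


class CollinearityError(ValueError):
    """Schedule points do not lie on a single line within tolerance."""


class ParallelCurvesError(ValueError):
    """Two curves have equal slope and therefore no unique intersection."""


class CurveRole(str, Enum):
    DEMAND = "demand"
    SUPPLY = "supply"


class BindingSide(str, Enum):
    """Which constraint determines the delivered volume."""

    CAPACITY_LIMITED = "capacity_limited"
    DEMAND_LIMITED = "demand_limited"
    BALANCED = "balanced"


def round_services(x: float) -> int:
    """Round a service volume to whole services, ties away from zero.

    The away-from-zero tie rule is the one consistent with the reference
    sensitivity grid (71.5 -> 72 and 84.5 -> 85; banker's rounding would
    give 84).  The input is first snapped to 9 decimals so that binary
    representation error in products like ``60 * 1.3`` cannot flip a tie.

    Raises
    ------
    DomainError
        If ``x`` is NaN or infinite.
    """
    if not math.isfinite(x):
        raise DomainError(f"cannot round non-finite service volume: {x!r}")
    snapped = round(float(x), 9)
    return int(Decimal(repr(snapped)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _check_bounds(name: str, low: float, base: float, high: float) -> None:
    if not (low <= base <= high):
        raise ValueError(
            f"{name}: bounds must satisfy low <= base <= high, "
            f"got low={low}, base={base}, high={high}"
        )


class ParameterSet(BaseModel):
    """The model's entire input surface.

    Defaults encode the 2023-2024 Alberta base case: a baseline of 60
    services/month, an additive demand shift of +27 services/month
    (bounds 20-35, calibrated from a reported +27.24/month utilization
    trend), a 30% proportional capacity expansion (bounds 20%-40%), and a
    reference unit-cost proxy of 150 CAD/service.  The user copayment is
    fixed at 0 CAD by policy design.
    """

    model_config = {"frozen": True}

    q0: float = Field(default=60.0, gt=0, description="baseline equilibrium quantity, services/month")
    delta_d: float = Field(default=27.0, description="additive demand shift, services/month")
    delta_d_bounds: Tuple[float, float] = Field(default=(20.0, 35.0))
    delta_c: float = Field(default=0.30, description="proportional capacity expansion, fraction")
    delta_c_bounds: Tuple[float, float] = Field(default=(0.20, 0.40))
    q0_bounds: Tuple[float, float] = Field(default=(55.0, 65.0))
    ref_proxy: float = Field(default=150.0, gt=0, description="reference unit-cost proxy, CAD/service")
    user_copay: float = Field(default=0.0, description="user-facing price, CAD (0 by policy design)")
    demand_slope: float = Field(default=DEFAULT_DEMAND_SLOPE, le=0)
    supply_slope: float = Field(default=DEFAULT_SUPPLY_SLOPE, ge=0)
    allow_contraction: bool = Field(
        default=False,
        description="permit negative delta_d / delta_c (explicit contraction scenarios)",
    )
    calibration_note: str = Field(
        default=(
            "Base case: demand shift +27 services/month from the reported "
            "+27.24/month youth GP mental-health visit trend; 30% proportional "
            "capacity expansion from reported 2023-2024 system scale-up."
        )
    )

    @model_validator(mode="after")
    def _validate(self) -> "ParameterSet":
        if self.user_copay != 0:
            raise ValueError("user_copay must be 0 CAD: the system is zero-copayment by design")
        if not self.allow_contraction:
            if self.delta_d < 0:
                raise ValueError("delta_d < 0 requires allow_contraction=True")
            if self.delta_c < 0:
                raise ValueError("delta_c < 0 requires allow_contraction=True")
        if self.delta_c <= -1:
            raise ValueError("delta_c must exceed -1 (capacity cannot go negative)")
        _check_bounds("delta_d", self.delta_d_bounds[0], self.delta_d, self.delta_d_bounds[1])
        _check_bounds("delta_c", self.delta_c_bounds[0], self.delta_c, self.delta_c_bounds[1])
        _check_bounds("q0", self.q0_bounds[0], self.q0, self.q0_bounds[1])
        return self


@dataclass(frozen=True)
class PriceQuantitySchedule:
    """An ordered grid of (price proxy, quantity) points for one curve.

    Points are normalized to ascending price-proxy order on construction;
    any presentation order (the demand table is conventionally printed with
    prices descending) is a rendering concern only.

    ``strict_monotone=False`` disables the role monotonicity check; it is
    used only for noisy synthetic schedules, whose pointwise perturbations
    need not preserve monotonicity.
    """

    role: CurveRole
    points: Tuple[Tuple[float, float], ...]
    label: str = ""
    strict_monotone: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("schedule needs at least one point")
        pts = tuple(sorted((float(p), float(q)) for p, q in self.points))
        object.__setattr__(self, "points", pts)
        prices = [p for p, _ in pts]
        if any(p <= 0 for p in prices):
            raise ValueError(f"price proxies must be positive, got {prices}")
        if any(prices[i] >= prices[i + 1] for i in range(len(prices) - 1)):
            raise ValueError("price proxies must be strictly increasing (duplicates found)")
        for p, q in pts:
            if q < 0:
                raise DomainError(
                    f"negative quantity {q} at price proxy {p} in {self.role.value} schedule"
                )
        if self.strict_monotone and len(pts) > 1:
            qs = [q for _, q in pts]
            if self.role is CurveRole.DEMAND:
                if any(qs[i + 1] > qs[i] + TOL for i in range(len(qs) - 1)):
                    raise ValueError("demand quantities must be non-increasing in the price proxy")
            else:
                if any(qs[i + 1] < qs[i] - TOL for i in range(len(qs) - 1)):
                    raise ValueError("supply quantities must be non-decreasing in the price proxy")

    @property
    def prices(self) -> Tuple[float, ...]:
        return tuple(p for p, _ in self.points)

    @property
    def quantities(self) -> Tuple[float, ...]:
        return tuple(q for _, q in self.points)

    def with_quantities(self, quantities: Sequence[float], label: Optional[str] = None) -> "PriceQuantitySchedule":
        if len(quantities) != len(self.points):
            raise ValueError("quantity list length must match the schedule grid")
        return PriceQuantitySchedule(
            role=self.role,
            points=tuple(zip(self.prices, (float(q) for q in quantities))),
            label=self.label if label is None else label,
            strict_monotone=self.strict_monotone,
        )


@dataclass(frozen=True)
class LinearCurve:
    """Slope/intercept form of a demand or supply line.

    ``quantity = intercept + slope * price_proxy``; demand slopes are
    non-positive, supply slopes non-negative.
    """

    role: CurveRole
    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.role is CurveRole.DEMAND and self.slope > TOL:
            raise ValueError(f"demand curve requires slope <= 0, got {self.slope}")
        if self.role is CurveRole.SUPPLY and self.slope < -TOL:
            raise ValueError(f"supply curve requires slope >= 0, got {self.slope}")

    def __call__(self, price_proxy: float) -> float:
        return self.intercept + self.slope * price_proxy


@dataclass(frozen=True)
class EquilibriumResult:
    """Delivered volume and unmet demand under the capacity constraint."""

    demand_implied: float
    capacity_implied: float
    delivered: int
    unmet: int
    binding: BindingSide


@dataclass(frozen=True)
class IntersectionPoint:
    """Solution of demand == supply; ``feasible`` is False when the solution
    lies at a negative proxy or quantity (flagged rather than silently
    returned)."""

    price_proxy: float
    quantity: float
    feasible: bool


def _build_schedule(
    params: ParameterSet, grid: Sequence[float], role: CurveRole, slope: float, label: str
) -> PriceQuantitySchedule:
    if len(grid) == 0:
        raise ValueError("price-proxy grid must be non-empty")
    if any(p <= 0 for p in grid):
        raise ValueError(f"price-proxy grid must be strictly positive, got {list(grid)}")
    points = []
    for p in grid:
        q = params.q0 + slope * (float(p) - params.ref_proxy)
        if q < 0:
            raise DomainError(
                f"{role.value} quantity would be negative ({q:.6g}) at price proxy {p}; "
                "adjust the grid or slope rather than clipping"
            )
        points.append((float(p), q))
    return PriceQuantitySchedule(role=role, points=tuple(points), label=label)


def build_demand_schedule(params: ParameterSet, grid: Sequence[float]) -> PriceQuantitySchedule:
    """Construct the baseline (pre-shift) demand schedule on ``grid``.

    The line has slope ``params.demand_slope`` and is anchored to pass
    through ``(ref_proxy, q0)``, so varying the baseline quantity moves the
    whole curve coherently.
    """
    return _build_schedule(params, grid, CurveRole.DEMAND, params.demand_slope, "pre-COVID demand")


def build_supply_schedule(params: ParameterSet, grid: Sequence[float]) -> PriceQuantitySchedule:
    """Construct the baseline (pre-shift) supply schedule on ``grid``,
    anchored through ``(ref_proxy, q0)`` with slope ``params.supply_slope``."""
    return _build_schedule(params, grid, CurveRole.SUPPLY, params.supply_slope, "pre-COVID supply")


def shift_demand_additive(
    schedule: PriceQuantitySchedule, delta_d: float
) -> PriceQuantitySchedule:
    """Shift a demand schedule rightward by adding ``delta_d`` services/month
    at every price-proxy level (exactly; no rounding is applied)."""
    if schedule.role is not CurveRole.DEMAND:
        raise RoleError("additive demand shift requires a demand schedule")
    return schedule.with_quantities(
        [q + delta_d for q in schedule.quantities], label="post-COVID demand"
    )


def shift_supply_proportional(
    schedule: PriceQuantitySchedule, delta_c: float
) -> PriceQuantitySchedule:
    """Expand a supply schedule proportionally: post = round(pre * (1+delta_c))
    at every grid point, rounded to whole services."""
    if schedule.role is not CurveRole.SUPPLY:
        raise RoleError("proportional capacity expansion requires a supply schedule")
    if delta_c <= -1:
        raise DomainError(f"delta_c must exceed -1, got {delta_c}")
    return schedule.with_quantities(
        [round_services(q * (1.0 + delta_c)) for q in schedule.quantities],
        label="post-COVID supply",
    )


def classify_binding(demand_implied: float, capacity_implied: float) -> BindingSide:
    """Which side binds, compared before rounding: capacity-limited when the
    demand-implied volume exceeds the capacity-implied volume, balanced when
    they agree within 1e-9."""
    if not (math.isfinite(demand_implied) and math.isfinite(capacity_implied)):
        raise DomainError("binding classification requires finite volumes")
    if abs(demand_implied - capacity_implied) <= TOL:
        return BindingSide.BALANCED
    if demand_implied > capacity_implied:
        return BindingSide.CAPACITY_LIMITED
    return BindingSide.DEMAND_LIMITED


def delivered_volume(q0: float, delta_d: float, delta_c: float) -> EquilibriumResult:
    """Compute the capacity-constrained delivered volume.

    ``Q* = min(q0 + delta_d, q0 * (1 + delta_c))``, rounded to whole
    services *after* taking the minimum.  Unmet demand is the rounded
    demand-implied volume minus Q* (zero unless capacity binds).
    """
    if q0 <= 0:
        raise DomainError(f"baseline quantity must be positive, got {q0}")
    demand_implied = q0 + delta_d
    capacity_implied = q0 * (1.0 + delta_c)
    delivered = round_services(min(demand_implied, capacity_implied))
    unmet = round_services(demand_implied) - delivered
    if unmet < 0:  # can only arise from the rounding of near-equal volumes
        unmet = 0
    return EquilibriumResult(
        demand_implied=demand_implied,
        capacity_implied=capacity_implied,
        delivered=delivered,
        unmet=unmet,
        binding=classify_binding(demand_implied, capacity_implied),
    )


def fit_linear_curve(schedule: PriceQuantitySchedule) -> LinearCurve:
    """Recover the line implied by a schedule grid.

    The slope is taken from the two endpoints and every interior point must
    lie on that line within 1e-9 services/month; otherwise the fit fails
    with the maximum residual reported.
    """
    if len(schedule.points) < 2:
        raise ValueError("fitting a line requires at least two points")
    (p0, q0), (pn, qn) = schedule.points[0], schedule.points[-1]
    slope = (qn - q0) / (pn - p0)
    intercept = q0 - slope * p0
    residuals = [abs(q - (intercept + slope * p)) for p, q in schedule.points]
    worst = max(residuals)
    if worst > TOL:
        raise CollinearityError(
            f"schedule points are not collinear: max residual {worst:.3e} services/month"
        )
    return LinearCurve(role=schedule.role, intercept=intercept, slope=slope)


def curve_intersection(demand: LinearCurve, supply: LinearCurve) -> IntersectionPoint:
    """Solve demand(p) == supply(p) for the equilibrium point.

    Note that the headline delivered-volume figure does *not* come from
    re-solving the post-shift intersection; the pipeline's default mode
    evaluates both post-shift curves at the fixed reference proxy and
    applies the min rule.  Intersection solving is the baseline-equilibrium
    check and an exposed extension.
    """
    if abs(demand.slope - supply.slope) <= TOL:
        raise ParallelCurvesError("curves are parallel: no unique intersection")
    p = (demand.intercept - supply.intercept) / (supply.slope - demand.slope)
    q = demand(p)
    return IntersectionPoint(price_proxy=p, quantity=q, feasible=(p >= 0 and q >= 0))
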