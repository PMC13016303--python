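"""Seeded generators for parameter sets and linear price-quantity schedules.

These generators emulate the structural assumptions of the model — an
additive demand shift, a proportional capacity expansion, and linear
demand/supply schedules anchored at a common reference point — so that
every pipeline stage can be exercised without external data.  Parameters
are drawn uniformly within their declared ranges (the model states bounds,
never distributions; uniform is the least-committal choice and is trivially
swappable).  Schedules are exactly linear by default; additive Gaussian
noise on quantities is available as an explicit opt-in.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model_core import (
    CurveRole,
    DomainError,
    ParameterSet,
    PriceQuantitySchedule,
)

__all__ = ["SyntheticSpec", "generate_parameter_sets", "generate_schedule_pair"]

_MAX_RESAMPLE = 100


class SyntheticSpec(BaseModel):
    """Sampling ranges and grid layout for synthetic model inputs.

    Default ranges bracket the base-case calibration (baseline 60
    services/month, demand shift +27, capacity expansion 30%, slope
    magnitude 0.4) widely enough to exercise both binding regimes.
    """

    model_config = {"frozen": True}

    n: int = Field(default=100, ge=1, description="number of parameter sets")
    seed: int = Field(default=0, ge=0)
    q0_range: Tuple[float, float] = Field(default=(40.0, 80.0))
    delta_d_range: Tuple[float, float] = Field(default=(10.0, 40.0))
    delta_c_range: Tuple[float, float] = Field(default=(0.1, 0.5))
    slope_magnitude_range: Tuple[float, float] = Field(default=(0.2, 0.6))
    grid_spec: Tuple[float, float, float] = Field(
        default=(50.0, 250.0, 50.0), description="(start, stop, step), CAD/service"
    )
    ref_proxy: float = Field(default=150.0, gt=0)
    noise_sd: float = Field(default=0.0, ge=0, description="services/month; 0 = exact linearity")

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticSpec":
        for name in ("q0_range", "delta_d_range", "delta_c_range", "slope_magnitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
        if self.q0_range[0] <= 0:
            raise ValueError("q0_range must be strictly positive")
        start, stop, step = self.grid_spec
        if start <= 0 or step <= 0 or stop < start + step:
            raise ValueError("grid_spec must yield >= 2 strictly positive points")
        return self

    def grid(self) -> np.ndarray:
        start, stop, step = self.grid_spec
        return np.arange(start, stop + step / 2, step)


def _uniform(rng: np.random.Generator, bounds: Tuple[float, float]) -> float:
    lo, hi = bounds
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def generate_parameter_sets(spec: SyntheticSpec) -> List[ParameterSet]:
    """Draw ``spec.n`` parameter sets uniformly within the spec's ranges.

    Each set's bounds are drawn around its base value (low in
    [range_min, base], high in [base, range_max]) so every set satisfies
    the ordered-bounds invariant.  Identical seeds yield identical output.
    """
    rng = np.random.default_rng(spec.seed)
    out: List[ParameterSet] = []
    for _ in range(spec.n):
        q0 = _uniform(rng, spec.q0_range)
        dd = _uniform(rng, spec.delta_d_range)
        dc = _uniform(rng, spec.delta_c_range)
        q0_b = (_uniform(rng, (spec.q0_range[0], q0)), _uniform(rng, (q0, spec.q0_range[1])))
        dd_b = (_uniform(rng, (spec.delta_d_range[0], dd)), _uniform(rng, (dd, spec.delta_d_range[1])))
        dc_b = (_uniform(rng, (spec.delta_c_range[0], dc)), _uniform(rng, (dc, spec.delta_c_range[1])))
        out.append(
            ParameterSet(
                q0=q0,
                delta_d=dd,
                delta_c=dc,
                q0_bounds=q0_b,
                delta_d_bounds=dd_b,
                delta_c_bounds=dc_b,
                ref_proxy=spec.ref_proxy,
                calibration_note=f"synthetic draw (seed={spec.seed})",
            )
        )
    return out


def generate_schedule_pair(
    params: ParameterSet,
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PriceQuantitySchedule, PriceQuantitySchedule]:
    """Generate one anchored demand/supply schedule pair.

    Both lines pass through ``(ref_proxy, q0)``; the demand slope is a
    negated draw and the supply slope a positive draw from the spec's
    slope-magnitude range, so the noiseless pair intersects exactly at the
    anchor.  With ``noise_sd > 0``, independent Gaussian perturbations are
    added to every quantity; a draw producing a negative quantity anywhere
    on the grid is rejected and the slopes (and noise) redrawn, up to a
    bounded retry count, after which an error is raised.
    Monotonicity is not enforced on noisy schedules.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    quantities = None
    for _ in range(_MAX_RESAMPLE):
        m_d = _uniform(rng, spec.slope_magnitude_range)
        m_s = _uniform(rng, spec.slope_magnitude_range)
        draw = {
            CurveRole.DEMAND: params.q0 - m_d * (grid - params.ref_proxy),
            CurveRole.SUPPLY: params.q0 + m_s * (grid - params.ref_proxy),
        }
        if spec.noise_sd > 0:
            for role in draw:
                draw[role] = draw[role] + rng.normal(0.0, spec.noise_sd, size=len(grid))
        if all(np.all(q >= 0) for q in draw.values()):
            quantities = draw
            break
    if quantities is None:
        raise DomainError(
            f"could not draw a non-negative schedule pair in {_MAX_RESAMPLE} "
            f"attempts (q0={params.q0}, noise_sd={spec.noise_sd}); widen the "
            "quantity ranges or shrink the slope magnitudes"
        )
    schedules = {
        role: PriceQuantitySchedule(
            role=role,
            points=tuple(zip(grid.tolist(), q.tolist())),
            label=f"synthetic {role.value}",
            strict_monotone=(spec.noise_sd == 0),
        )
        for role, q in quantities.items()
    }
    return schedules[CurveRole.DEMAND], schedules[CurveRole.SUPPLY]
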