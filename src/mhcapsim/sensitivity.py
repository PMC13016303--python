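"""Deterministic one-way sensitivity analysis and multi-way scenario checks.

One parameter is varied at a time between its declared low/high bounds while
all others stay at base values; each cell is an independent delivered-volume
computation.  Multi-way scenarios vary capacity expansion and demand shift
jointly (e.g. low capacity + high demand) to probe which side binds.
Probabilistic sensitivity analysis is deliberately out of scope: the model
is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .model_core import (
    BindingSide,
    ParameterSet,
    classify_binding,
    delivered_volume,
)

__all__ = [
    "SensitivityRow",
    "ScenarioSpec",
    "INTERPRETATION_LABELS",
    "DEFAULT_SCENARIOS",
    "one_way_dsa",
    "scenario_grid",
    "classify_binding",
]

log = logging.getLogger(__name__)

#: Machine-comparable interpretation labels attached to binding outcomes.
INTERPRETATION_LABELS = {
    BindingSide.CAPACITY_LIMITED: "congestion/unmet demand likely (demand exceeds deliverable capacity)",
    BindingSide.DEMAND_LIMITED: "capacity sufficient; delivered volume limited by demand",
    BindingSide.BALANCED: "demand-implied and capacity-implied volumes coincide",
}

#: The two joint-variation scenarios pairing opposite bounds.
DEFAULT_SCENARIOS: Tuple[Tuple[str, float, float], ...] = (
    ("Capacity-limited (low capacity + high demand)", 0.20, 35.0),
    ("Demand-limited (high capacity + low demand)", 0.40, 20.0),
)


@dataclass(frozen=True)
class SensitivityRow:
    """One one-way sensitivity row: a parameter varied across its bounds."""

    parameter: str  # capacity_expansion | demand_increase | baseline_q0
    base_value: float
    low_value: float
    high_value: float
    q_base: int
    q_low: int
    q_high: int
    binding_base: BindingSide
    binding_low: BindingSide
    binding_high: BindingSide

    @property
    def interpretation(self) -> Tuple[str, str, str]:
        """Binding-side labels at (base, low, high)."""
        return (
            INTERPRETATION_LABELS[self.binding_base],
            INTERPRETATION_LABELS[self.binding_low],
            INTERPRETATION_LABELS[self.binding_high],
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One multi-way scenario: joint (delta_c, delta_d) and its outcome."""

    name: str
    delta_c: float
    delta_d: float
    delivered: int
    binding: BindingSide

    @property
    def interpretation(self) -> str:
        return INTERPRETATION_LABELS[self.binding]


def _row(
    parameter: str,
    base: float,
    low: float,
    high: float,
    results,
) -> SensitivityRow:
    r_base, r_low, r_high = results
    return SensitivityRow(
        parameter=parameter,
        base_value=base,
        low_value=low,
        high_value=high,
        q_base=r_base.delivered,
        q_low=r_low.delivered,
        q_high=r_high.delivered,
        binding_base=r_base.binding,
        binding_low=r_low.binding,
        binding_high=r_high.binding,
    )


def one_way_dsa(params: ParameterSet) -> List[SensitivityRow]:
    """Run the three one-way sensitivity rows: capacity expansion, demand
    increase, and baseline quantity.

    Each cell substitutes the bound value while holding the other two
    parameters at base.  Varying the baseline quantity rescales *both* the
    demand-implied (q0 + delta_d) and capacity-implied (q0 * (1 + delta_c))
    volumes; the delivered volume remains the minimum of the two.
    """
    q0, dd, dc = params.q0, params.delta_d, params.delta_c
    dc_lo, dc_hi = params.delta_c_bounds
    dd_lo, dd_hi = params.delta_d_bounds
    q0_lo, q0_hi = params.q0_bounds

    rows = [
        _row(
            "capacity_expansion",
            dc,
            dc_lo,
            dc_hi,
            (
                delivered_volume(q0, dd, dc),
                delivered_volume(q0, dd, dc_lo),
                delivered_volume(q0, dd, dc_hi),
            ),
        ),
        _row(
            "demand_increase",
            dd,
            dd_lo,
            dd_hi,
            (
                delivered_volume(q0, dd, dc),
                delivered_volume(q0, dd_lo, dc),
                delivered_volume(q0, dd_hi, dc),
            ),
        ),
        _row(
            "baseline_q0",
            q0,
            q0_lo,
            q0_hi,
            (
                delivered_volume(q0, dd, dc),
                delivered_volume(q0_lo, dd, dc),
                delivered_volume(q0_hi, dd, dc),
            ),
        ),
    ]
    return rows


def scenario_grid(
    params: ParameterSet,
    scenarios: Iterable[Tuple[str, float, float]] = DEFAULT_SCENARIOS,
) -> List[ScenarioSpec]:
    """Evaluate joint (delta_c, delta_d) scenarios at the base q0.

    Scenario values outside the declared bounds are evaluated anyway with a
    logged warning (scenario grids pair bound values freely; an out-of-range
    probe is a legitimate robustness check, not an error).
    """
    scenarios = list(scenarios)
    if not scenarios:
        log.warning("empty scenario list: returning no scenario rows")
        return []
    dc_lo, dc_hi = params.delta_c_bounds
    dd_lo, dd_hi = params.delta_d_bounds
    out: List[ScenarioSpec] = []
    for name, delta_c, delta_d in scenarios:
        if not (dc_lo <= delta_c <= dc_hi):
            log.warning(
                "scenario %r: delta_c=%s outside declared bounds [%s, %s]",
                name, delta_c, dc_lo, dc_hi,
            )
        if not (dd_lo <= delta_d <= dd_hi):
            log.warning(
                "scenario %r: delta_d=%s outside declared bounds [%s, %s]",
                name, delta_d, dd_lo, dd_hi,
            )
        res = delivered_volume(params.q0, delta_d, delta_c)
        out.append(
            ScenarioSpec(
                name=name,
                delta_c=delta_c,
                delta_d=delta_d,
                delivered=res.delivered,
                binding=res.binding,
            )
        )
    return out
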