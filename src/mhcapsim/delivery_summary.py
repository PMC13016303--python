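"""Planned-vs-actual program-delivery summaries (empirical 2023-2024 data).

This module houses the observed program-delivery table for Alberta's
2023-2024 reporting period as a typed fixture and computes per-program
attainment summaries.  Planned targets and actuals are only compared when a
numeric planned target exists *in the same delivery unit* as an actual;
narrative targets (funding amounts, multi-year goals) are carried as text
and excluded from ratios.  Units differ by program because the source
reports each program in its own delivery unit (students, admissions,
clients, sessions, beds, classrooms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple

__all__ = [
    "UNITS",
    "MetricComparison",
    "ProgramDeliveryRecord",
    "DeliverySummaryRow",
    "NOT_COMPARABLE",
    "load_delivery_fixture",
    "summarize_delivery",
    "classify_program",
]

UNITS = frozenset({"students", "clients", "admissions", "sessions", "beds", "classrooms"})

#: Sentinel classification for records without a unit-matched numeric target.
NOT_COMPARABLE = "not comparable"


@dataclass(frozen=True)
class MetricComparison:
    """One planned/actual pair in a single delivery unit.

    Either side may be absent (``None``): several programs report an actual
    with no numeric target, and some targets have no reported actual in the
    same unit.  ``approximate`` marks actuals the source prints with a tilde
    (e.g. "~12,300 sessions").
    """

    unit: str
    planned: Optional[float] = None
    actual: Optional[float] = None
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown delivery unit {self.unit!r}; expected one of {sorted(UNITS)}")
        if self.planned is not None and self.planned <= 0:
            raise ValueError(f"planned target must be positive when present, got {self.planned}")
        if self.actual is not None and self.actual < 0:
            raise ValueError(f"actual value must be non-negative, got {self.actual}")


@dataclass(frozen=True)
class ProgramDeliveryRecord:
    """One program's planned/funded expansion and reported delivery.

    ``metrics`` lists the program's unit-level comparisons; the first metric
    is the program's headline delivery figure (``actual_value`` / ``unit``).
    """

    program: str
    planned_description: str
    metrics: Tuple[MetricComparison, ...]
    outcome_note: str = ""
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError(f"{self.program}: at least one metric is required")
        if self.metrics[0].actual is None:
            raise ValueError(f"{self.program}: headline metric must carry an actual value")

    @property
    def actual_value(self) -> float:
        return self.metrics[0].actual  # type: ignore[return-value]

    @property
    def unit(self) -> str:
        return self.metrics[0].unit

    @property
    def planned_target(self) -> Optional[float]:
        """First numeric planned target, if any metric carries one."""
        for m in self.metrics:
            if m.planned is not None:
                return m.planned
        return None


@dataclass(frozen=True)
class DeliverySummaryRow:
    """Attainment for one program/unit pair."""

    program: str
    unit: str
    planned: Optional[float]
    actual: Optional[float]
    comparable: bool
    met_plan: Optional[bool]  # None when not comparable
    attainment_ratio: Optional[float]
    approximate: bool = False


def load_delivery_fixture() -> List[ProgramDeliveryRecord]:
    """Load the shipped 2023-2024 program-delivery table."""
    raw = resources.files("mhcapsim.data").joinpath("program_delivery.json").read_text()
    records = []
    for entry in json.loads(raw):
        metrics = tuple(MetricComparison(**m) for m in entry.pop("metrics"))
        records.append(ProgramDeliveryRecord(metrics=metrics, **entry))
    return records


def summarize_delivery(
    records: Sequence[ProgramDeliveryRecord],
) -> List[DeliverySummaryRow]:
    """Compute planned-vs-actual attainment rows, one per program/unit pair.

    A pair is *comparable* only when both a numeric planned target and an
    actual exist in the same unit; then ``met_plan = actual >= planned`` and
    the attainment ratio is actual/planned.  A planned target with no
    same-unit actual (or vice versa) is never divided across units.
    """
    if not records:
        raise ValueError("record list must be non-empty")
    rows: List[DeliverySummaryRow] = []
    for rec in records:
        for m in rec.metrics:
            comparable = m.planned is not None and m.actual is not None
            rows.append(
                DeliverySummaryRow(
                    program=rec.program,
                    unit=m.unit,
                    planned=m.planned,
                    actual=m.actual,
                    comparable=comparable,
                    met_plan=(m.actual >= m.planned) if comparable else None,  # type: ignore[operator]
                    attainment_ratio=(m.actual / m.planned) if comparable else None,  # type: ignore[operator]
                    approximate=m.approximate,
                )
            )
    return rows


def classify_program(rows: Sequence[DeliverySummaryRow], program: str) -> str:
    """Program-level classification from its comparable unit pairs.

    ``"met plan"`` when every comparable pair met its target, ``"below
    plan"`` when any fell short, and ``"not comparable"`` when the program
    has no unit-matched numeric target at all.
    """
    mine = [r for r in rows if r.program == program and r.comparable]
    if not mine:
        return NOT_COMPARABLE
    return "met plan" if all(r.met_plan for r in mine) else "below plan"
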