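"""Config parsing, table rendering and plotting.

Configs are YAML (or JSON) documents carrying the model parameters with
their bounds, the price-proxy grid, and optional scenario definitions.
Percent notation ("30%") is accepted for the capacity expansion at the
config boundary and converted to a fraction with a logged note.  Rendered
CSV/JSON outputs are deterministic: identical inputs produce byte-identical
files, and run metadata goes to the log, never into data files.

All monetary columns are CAD for the 2023-2024 reporting period; no
inflation or purchasing-power-parity adjustment is applied anywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .model_core import (
    ParameterSet,
    PriceQuantitySchedule,
    build_demand_schedule,
    build_supply_schedule,
    delivered_volume,
    shift_demand_additive,
    shift_supply_proportional,
)
from .sensitivity import DEFAULT_SCENARIOS, ScenarioSpec, SensitivityRow, one_way_dsa, scenario_grid

__all__ = [
    "ConfigError",
    "RunConfig",
    "DEFAULT_GRID",
    "CURRENCY_NOTE",
    "load_config",
    "render_tables",
    "plot_curves",
]

log = logging.getLogger(__name__)

DEFAULT_GRID: Tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 250.0)

CURRENCY_NOTE = "CAD, 2023-2024, unadjusted (no inflation/PPP adjustment)"

_KNOWN_KEYS = {
    "q0",
    "delta_d",
    "delta_c",
    "ref_proxy",
    "grid",
    "demand_slope",
    "supply_slope",
    "scenarios",
    "output_dir",
    "seed",
    "emit_plots",
}

_DSA_LABELS = {
    "capacity_expansion": "Capacity expansion (system)",
    "demand_increase": "Demand increase (system)",
    "baseline_q0": "Baseline equilibrium quantity (Q0)",
}


class ConfigError(ValueError):
    """Raised with every failing config field listed, not just the first."""


class RunConfig(BaseModel):
    """A fully validated pipeline run: parameters, grid, scenarios, output."""

    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    parameters: ParameterSet = Field(default_factory=ParameterSet)
    grid: Tuple[float, ...] = Field(default=DEFAULT_GRID)
    scenarios: Tuple[Tuple[str, float, float], ...] = Field(default=DEFAULT_SCENARIOS)
    output_dir: Path = Field(default=Path("out"))
    seed: Optional[int] = None
    emit_plots: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "RunConfig":
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if any(p <= 0 for p in self.grid):
            raise ValueError(f"grid proxies must be strictly positive, got {list(self.grid)}")
        return self


def _parse_fraction(value: Union[str, float, int], where: str, errors: List[str]) -> float:
    """Accept 0.30 or '30%' for proportional parameters."""
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            try:
                frac = float(s[:-1]) / 100.0
            except ValueError:
                errors.append(f"{where}: cannot parse percent value {value!r}")
                return 0.0
            log.info("%s: converted percent notation %r to fraction %s", where, value, frac)
            return frac
        errors.append(f"{where}: expected a fraction (e.g. 0.30) or percent string (e.g. '30%'), got {value!r}")
        return 0.0
    return float(value)


def _parse_bounded(
    raw: object, name: str, units: str, errors: List[str], fraction: bool = False
) -> Tuple[Optional[float], Optional[Tuple[float, float]]]:
    """Parse a scalar or a {base, low, high} mapping.  Returns (base, bounds);
    either may be None when the key was absent or malformed."""
    if raw is None:
        return None, None
    parse = (lambda v, w: _parse_fraction(v, w, errors)) if fraction else (lambda v, w: float(v))
    if isinstance(raw, dict):
        unknown = set(raw) - {"base", "low", "high"}
        if unknown:
            errors.append(f"{name}: unknown sub-keys {sorted(unknown)} (expected base/low/high, {units})")
            return None, None
        base = parse(raw["base"], f"{name}.base") if "base" in raw else None
        low = parse(raw["low"], f"{name}.low") if "low" in raw else None
        high = parse(raw["high"], f"{name}.high") if "high" in raw else None
        bounds = None
        if low is not None and high is not None:
            if low > high:
                errors.append(f"{name}: bounds reversed, low={low} > high={high} ({units})")
            else:
                bounds = (low, high)
        elif (low is None) != (high is None):
            errors.append(f"{name}: low and high bounds must be given together ({units})")
        return base, bounds
    try:
        return parse(raw, name), None
    except (TypeError, ValueError):
        errors.append(f"{name}: expected a number ({units}), got {raw!r}")
        return None, None


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Omitted fields default to the base-case calibration.  Unknown keys are
    an error (never silently ignored), and every failing field is reported
    with its expected units in a single :class:`ConfigError`.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping, got {type(doc).__name__}")

    errors: List[str] = []
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")

    q0_base, q0_bounds = _parse_bounded(doc.get("q0"), "q0", "services/month", errors)
    dd_base, dd_bounds = _parse_bounded(doc.get("delta_d"), "delta_d", "services/month", errors)
    dc_base, dc_bounds = _parse_bounded(
        doc.get("delta_c"), "delta_c", "fraction or percent", errors, fraction=True
    )

    param_kwargs: Dict[str, object] = {}
    for key, value in (
        ("q0", q0_base),
        ("q0_bounds", q0_bounds),
        ("delta_d", dd_base),
        ("delta_d_bounds", dd_bounds),
        ("delta_c", dc_base),
        ("delta_c_bounds", dc_bounds),
    ):
        if value is not None:
            param_kwargs[key] = value
    if "ref_proxy" in doc:
        param_kwargs["ref_proxy"] = doc["ref_proxy"]
    if "demand_slope" in doc:
        param_kwargs["demand_slope"] = doc["demand_slope"]
    if "supply_slope" in doc:
        param_kwargs["supply_slope"] = doc["supply_slope"]

    scenarios = None
    if "scenarios" in doc:
        scenarios = []
        for i, sc in enumerate(doc["scenarios"] or []):
            if not isinstance(sc, dict) or not {"name", "delta_c", "delta_d"} <= set(sc):
                errors.append(f"scenarios[{i}]: expected mapping with name, delta_c, delta_d")
                continue
            scenarios.append(
                (
                    str(sc["name"]),
                    _parse_fraction(sc["delta_c"], f"scenarios[{i}].delta_c", errors),
                    float(sc["delta_d"]),
                )
            )

    if errors:
        raise ConfigError(f"{path}: invalid configuration:\n  - " + "\n  - ".join(errors))

    try:
        params = ParameterSet(**param_kwargs)
        cfg_kwargs: Dict[str, object] = {"parameters": params}
        if "grid" in doc:
            cfg_kwargs["grid"] = tuple(float(p) for p in doc["grid"])
        if scenarios is not None:
            cfg_kwargs["scenarios"] = tuple(scenarios)
        if "output_dir" in doc:
            cfg_kwargs["output_dir"] = Path(doc["output_dir"])
        if "seed" in doc:
            cfg_kwargs["seed"] = int(doc["seed"])
        if "emit_plots" in doc:
            cfg_kwargs["emit_plots"] = bool(doc["emit_plots"])
        return RunConfig(**cfg_kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: invalid configuration: {exc}") from exc


def _fmt_qty(q: float) -> str:
    """Render a quantity: integer when integral (all reference grids are)."""
    r = round(q)
    return str(int(r)) if abs(q - r) < 1e-9 else f"{q:.6g}"


def _fmt_pct(frac: float) -> str:
    pct = frac * 100
    return f"{int(round(pct))}%" if abs(pct - round(pct)) < 1e-9 else f"{pct:.4g}%"


def _fmt_signed(x: float) -> str:
    return f"+{_fmt_qty(x)}" if x >= 0 else f"-{_fmt_qty(-x)}"


def _write(path: Path, lines: Sequence[str]) -> None:
    path.write_text("\n".join(lines) + "\n")


def _demand_csv(pre: PriceQuantitySchedule, post: PriceQuantitySchedule) -> List[str]:
    lines = [
        "Price proxy (CAD/service),Quantity demanded (pre-COVID),Quantity demanded (post-COVID)"
    ]
    # demand is conventionally printed with prices descending
    for (p, q_pre), (_, q_post) in zip(reversed(pre.points), reversed(post.points)):
        lines.append(f"{_fmt_qty(p)},{_fmt_qty(q_pre)},{_fmt_qty(q_post)}")
    return lines


def _supply_csv(pre: PriceQuantitySchedule, post: PriceQuantitySchedule) -> List[str]:
    lines = [
        "Price proxy (CAD/service),Quantity supplied (pre-COVID),Quantity supplied (post-COVID)"
    ]
    for (p, q_pre), (_, q_post) in zip(pre.points, post.points):
        lines.append(f"{_fmt_qty(p)},{_fmt_qty(q_pre)},{_fmt_qty(q_post)}")
    return lines


def _dsa_csv(rows: Sequence[SensitivityRow]) -> List[str]:
    lines = ["Parameter,Base,Low,High,Q*_base,Q*_low,Q*_high"]
    for r in rows:
        if r.parameter == "capacity_expansion":
            fmt = _fmt_pct
        elif r.parameter == "demand_increase":
            fmt = _fmt_signed
        else:
            fmt = _fmt_qty
        lines.append(
            f"{_DSA_LABELS[r.parameter]},{fmt(r.base_value)},{fmt(r.low_value)},"
            f"{fmt(r.high_value)},{r.q_base},{r.q_low},{r.q_high}"
        )
    return lines


def _scenarios_csv(rows: Sequence[ScenarioSpec]) -> List[str]:
    lines = ["Scenario,Capacity,Demand,Delivered"]
    for r in rows:
        lines.append(f"{r.name},{_fmt_pct(r.delta_c)},{_fmt_signed(r.delta_d)},{r.delivered}")
    return lines


def render_tables(config: RunConfig, out_dir: Optional[Union[str, Path]] = None) -> Dict[str, Path]:
    """Run the full pipeline and write its tabular outputs.

    Writes ``demand_table.csv``, ``supply_table.csv``, ``dsa_table.csv``,
    ``scenarios_table.csv`` and ``equilibrium.json`` under ``out_dir``
    (defaults to the config's ``output_dir``).  Re-running on identical
    inputs produces byte-identical files.
    """
    out = Path(out_dir) if out_dir is not None else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise OSError(f"output directory {out} is not writable")

    params = config.parameters
    demand_pre = build_demand_schedule(params, config.grid)
    supply_pre = build_supply_schedule(params, config.grid)
    demand_post = shift_demand_additive(demand_pre, params.delta_d)
    supply_post = shift_supply_proportional(supply_pre, params.delta_c)
    eq = delivered_volume(params.q0, params.delta_d, params.delta_c)
    dsa_rows = one_way_dsa(params)
    scenario_rows = scenario_grid(params, config.scenarios)

    paths = {
        "demand_table": out / "demand_table.csv",
        "supply_table": out / "supply_table.csv",
        "dsa_table": out / "dsa_table.csv",
        "scenarios_table": out / "scenarios_table.csv",
        "equilibrium": out / "equilibrium.json",
    }
    _write(paths["demand_table"], _demand_csv(demand_pre, demand_post))
    _write(paths["supply_table"], _supply_csv(supply_pre, supply_post))
    _write(paths["dsa_table"], _dsa_csv(dsa_rows))
    _write(paths["scenarios_table"], _scenarios_csv(scenario_rows))

    eq_doc = {
        "currency": CURRENCY_NOTE,
        "q0": round(params.q0, 9),
        "ref_proxy": round(params.ref_proxy, 9),
        "demand_implied": round(eq.demand_implied, 9),
        "capacity_implied": round(eq.capacity_implied, 9),
        "delivered": eq.delivered,
        "unmet": eq.unmet,
        "binding": eq.binding.value,
    }
    paths["equilibrium"].write_text(json.dumps(eq_doc, indent=2, sort_keys=True) + "\n")

    if config.emit_plots:
        paths["plot"] = plot_curves(config, out / "curves.png")
    log.info("rendered %d output files to %s", len(paths), out)
    return paths


def plot_curves(config: RunConfig, path: Union[str, Path]) -> Path:
    """Plot pre/post demand and supply lines with the delivered volume marked.

    Plots are presentation output only and are excluded from determinism
    guarantees (PNG metadata may differ between runs).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = config.parameters
    demand_pre = build_demand_schedule(params, config.grid)
    supply_pre = build_supply_schedule(params, config.grid)
    demand_post = shift_demand_additive(demand_pre, params.delta_d)
    supply_post = shift_supply_proportional(supply_pre, params.delta_c)
    eq = delivered_volume(params.q0, params.delta_d, params.delta_c)

    fig, ax = plt.subplots(figsize=(7, 5))
    for sched, style, color in (
        (demand_pre, "--", "tab:blue"),
        (demand_post, "-", "tab:blue"),
        (supply_pre, "--", "tab:orange"),
        (supply_post, "-", "tab:orange"),
    ):
        ax.plot(sched.quantities, sched.prices, style, color=color, label=sched.label)
    ax.axhline(params.ref_proxy, color="grey", lw=0.8)
    ax.axvline(eq.delivered, color="black", lw=0.8, ls=":")
    ax.annotate(f"Q* = {eq.delivered}", (eq.delivered, params.ref_proxy), xytext=(5, 5),
                textcoords="offset points")
    ax.set_xlabel("Quantity (services/month)")
    ax.set_ylabel(f"Unit-cost proxy ({CURRENCY_NOTE})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
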