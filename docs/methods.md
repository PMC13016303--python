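# Methods

## Model

The package models a publicly financed mental-health system at the
aggregate level. Service volume is measured in services/month; "service"
means whatever delivery unit a program reports (sessions, admissions,
clients, …). The user-facing price is 0 CAD by policy design, so price
plays no allocative role; curves are drawn over a *unit-cost proxy*
(CAD/service) purely so that demand and supply mechanics can be displayed
in familiar axes. The proxy is not an observed price, and no inflation or
purchasing-power adjustment is applied — all monetary labels are CAD for
the 2023–2024 reporting period.

Both baseline curves are linear and anchored through the baseline
equilibrium (ref_proxy, q0). A shock is represented by two simultaneous
shifts:

- demand: additive, `D2(p) = D1(p) + delta_d`, exact (no rounding);
- capacity: proportional, `S2(p) = round(S1(p) * (1 + delta_c))`, rounded
  per point to whole services.

The post-shock delivered volume deliberately does **not** come from
re-solving the curve intersection. In a zero-copayment system the proxy
cannot adjust to clear the market, so the pipeline's default mode evaluates
both post-shift curves at the fixed reference proxy and applies the
capacity constraint:

    Q* = min(q0 + delta_d, q0 * (1 + delta_c)),  rounded after the min.

Unmet demand is `round(q0 + delta_d) − Q*` (zero when demand binds),
interpreted as congestion or queueing pressure, not extra utilization.
Intersection solving (`curve_intersection`) is exposed as an extension and
as the baseline consistency check — the pre-shift curves intersect at
(ref_proxy, q0) by construction — but solving the post-shift intersection
would answer a different question (it yields ≈83 services/month at a proxy
of ≈160 for the base case, i.e. a hypothetical market-clearing outcome that
the zero-copayment design rules out).

## Parameters

| parameter | meaning | unit | default | bounds |
|---|---|---|---|---|
| `q0` | baseline equilibrium quantity | services/month | 60 | 55–65 |
| `delta_d` | additive demand shift | services/month | +27 | 20–35 |
| `delta_c` | proportional capacity expansion | fraction | 0.30 | 0.20–0.40 |
| `ref_proxy` | reference unit-cost proxy | CAD/service | 150 | — |
| `demand_slope` | demand line slope | services/month per CAD/service | −0.4 | — |
| `supply_slope` | supply line slope | services/month per CAD/service | +0.4 | — |
| `user_copay` | user-facing price | CAD | 0 (fixed) | — |

The demand-shift default comes from a reported trend of +27.24/month in
youth GP mental-health visits per 100,000 after the initial pandemic drop;
the capacity default reflects the reported 2023–2024 system scale-up. The
±0.4 slopes are those implied by the equally spaced reference grids
(quantity changes by 20 services/month per 50 CAD/service step); whether
they are anything more than illustrative cannot be established from public
reporting, so they are stored as overridable defaults rather than
constants. Anchoring both curves through (ref_proxy, q0) makes the Q₀
sensitivity row move both curves coherently: varying Q₀ rescales both the
demand-implied and the capacity-implied volume, and Q* remains the minimum
of the two.

Percent notation ("30%") is accepted for `delta_c` at the config boundary
and converted to a fraction with a logged note; internally `delta_c` is
always a fraction.

## Numerical choices

- **Rounding.** `round_services` rounds to whole services with ties going
  *away from zero*, applied after the min. This is the only common tie
  rule consistent with both 71.5 → 72 and 84.5 → 85 in the sensitivity
  grid (banker's rounding would give 84). Inputs are snapped to 9 decimals
  first so binary representation error in products such as `60 * 1.3`
  cannot flip a tie.
- **Unmet demand** is computed post-rounding
  (`round(demand_implied) − Q*`). For the base case, pre- and post-rounding
  conventions agree (87 − 78 = 9); the convention matters for parameter
  sets where the demand-implied volume is fractional, and post-rounding
  keeps the conservation identity `round(demand) = delivered + unmet` exact
  in integers.
- **Binding side** is classified *before* rounding; volumes equal within
  1e-9 are "balanced".
- **Curve fitting** requires collinearity: the slope is taken from the grid
  endpoints and every point must sit on that line within 1e-9
  services/month, otherwise the fit fails reporting the maximum residual.
  A noisy grid is not silently averaged into a line.
- **Negative quantities** are construction errors, never clipped: the
  reference grids never go negative, and silent clipping would mask
  configuration mistakes.
- **Degenerate inputs**: single-point schedules are allowed (they carry a
  valid anchored evaluation) but cannot be fitted; parallel curves raise
  rather than returning an arbitrary point; an intersection at a negative
  proxy or quantity is returned with `feasible=False` rather than hidden.
- **Determinism**: rendered CSV/JSON outputs contain no timestamps or
  environment-dependent fields; re-running a configuration produces
  byte-identical files. Run metadata (config hash, version) goes to the
  stderr log. Plots are excluded from the determinism guarantee.

## Synthetic data

`synthetic_data` generates seeded parameter sets and anchored schedule
pairs with the same structural assumptions as the model: uniform draws
within declared ranges (the calibration states bounds, never
distributions, so uniform is the least-committal choice and is trivially
swappable), linear schedules through (ref_proxy, q0), and optional additive
Gaussian noise on quantities. Defaults (q0 ∈ [40, 80], delta_d ∈ [10, 40],
delta_c ∈ [0.1, 0.5], slope magnitude ∈ [0.2, 0.6], grid 50–250 step 50)
bracket the base calibration widely enough to exercise both binding
regimes. Noiseless generation is the default, matching the exactly linear
reference schedules; noisy mode exists to exercise the fitting error paths
and is exempt from the monotonicity invariant. A draw that would produce a
negative quantity anywhere on the grid is rejected and redrawn (slopes and
noise) up to 100 times, then raised as an error.

What the generator does **not** emulate: patient-level utilization,
waiting-list dynamics, program-specific caseloads, seasonal structure, or
any correlation between demand shifts and capacity expansion. Passing the
synthetic suites therefore shows that the arithmetic pipeline is internally
consistent over a broad parameter box, not that the linear/uniform
assumptions describe any real system.

## Sensitivity analysis

`one_way_dsa` produces exactly three rows (capacity expansion, demand
increase, baseline quantity); each cell substitutes one bound while holding
the other parameters at base and is an independent `delivered_volume`
call. The demand row is flat exactly when capacity binds at the lower
demand bound (base configuration: 78 < 60 + 20). `scenario_grid` evaluates
joint (delta_c, delta_d) pairs at the base q0; scenario values outside the
declared bounds are evaluated with a logged warning rather than rejected,
since pairing opposite bounds freely is the point of a scenario check.
Probabilistic (Monte Carlo) sensitivity analysis is intentionally out of
scope: the model is deterministic.

## Empirical delivery summary

The shipped fixture (`data/program_delivery.json`) records four 2023–2024
programs with planned expansions and reported actuals, each in the
program's own delivery unit. Attainment is computed only for unit-matched
numeric pairs; narrative targets (funding amounts, multi-year goals) are
carried as text and never divided. The "~12,300 sessions" tilde is stored
as an approximation flag, not dropped. Recovery communities report both
beds (125 of ~700 planned) and clients (219 of up-to-2,000/year), and the
summary reports both rather than choosing one. Programs without any
unit-matched numeric target (VODP admissions, tele-mental-health sessions)
are classified "not comparable" — the numeric classification is
deliberately more conservative than narrative source statements.

## Problem sizes

The property suites run 200 hypothesis examples per invariant
(derandomized) and the large-sample consistency checks use 1,000 synthetic
parameter draws; both were chosen as comfortably large for an arithmetic
model whose state space is three scalars, and the whole suite runs in a few
seconds on one CPU.

## Known limitations

- Linearity, the fixed proxy, and the min rule are modeling conventions,
  not estimates; the pipeline propagates assumptions, it does not infer
  parameters from data.
- No elasticity estimation, welfare/surplus computation, or
  cost-effectiveness analysis (ICER/QALY/budget impact) is provided — these
  require inputs that aggregate public reporting does not contain.
- The delivery fixture covers a single fiscal year and mixed units, so
  cross-program or cross-year comparisons are out of scope.
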