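{
  "binding": "capacity_limited",
  "capacity_implied": 78.0,
  "currency": "CAD, 2023-2024, unadjusted (no inflation/PPP adjustment)",
  "delivered": 78,
  "demand_implied": 87.0,
  "q0": 60.0,
  "ref_proxy": 150.0,
  "unmet": 9
}
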