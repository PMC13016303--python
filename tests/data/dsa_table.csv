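Parameter,Base,Low,High,Q*_base,Q*_low,Q*_high
Capacity expansion (system),30%,20%,40%,78,72,84
Demand increase (system),+27,+20,+35,78,78,78
Baseline equilibrium quantity (Q0),60,55,65,78,72,85
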