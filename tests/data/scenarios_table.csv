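Scenario,Capacity,Demand,Delivered
Capacity-limited (low capacity + high demand),20%,+35,72
Demand-limited (high capacity + low demand),40%,+20,80
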