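Price proxy (CAD/service),Quantity supplied (pre-COVID),Quantity supplied (post-COVID)
50,20,26
100,40,52
150,60,78
200,80,104
250,100,130
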