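Price proxy (CAD/service),Quantity demanded (pre-COVID),Quantity demanded (post-COVID)
250,20,47
200,40,67
150,60,87
100,80,107
50,100,127
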