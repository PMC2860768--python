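depth_um,loss_percent
37.8,11
51.6,17
67.6,20
68,23
77,27
99.2,30
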