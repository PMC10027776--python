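,x10,x12,x13
x10,1.187,0.537,0.375
x12,0.537,1.025,0.459
x13,0.375,0.459,1.018
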