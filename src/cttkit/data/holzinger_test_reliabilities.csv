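variable,r_xx
x06,0.700
x07,0.790
x09,0.860
x10,0.955
x12,0.930
x13,0.885
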