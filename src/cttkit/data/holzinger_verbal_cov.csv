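,x06,x07,x09
x06,1.355,1.101,0.899
x07,1.101,1.665,1.018
x09,0.899,1.018,1.200
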