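group,1,2,3,4
A,2.0,3.0,4.0,5.0
B,1.0,2.0,3.0,4.0
C,1.0,2.0,3.0,4.0
D,0.5,1.0,1.5,2.0
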