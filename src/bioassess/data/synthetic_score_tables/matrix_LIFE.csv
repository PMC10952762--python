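group,1,2,3,4
I,9.0,10.0,11.0,12.0
II,8.0,9.0,10.0,11.0
III,7.0,7.0,7.0,7.0
IV,6.0,5.0,4.0,3.0
V,5.0,4.0,3.0,2.0
VI,4.0,3.0,2.0,1.0
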