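level,A_hours,B_per_mm
0.90,5.72,1.04
0.95,7.17,1.12
0.99,11.3,1.16
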