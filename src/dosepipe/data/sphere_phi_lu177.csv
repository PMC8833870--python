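mass_g,phi
0.1,0.70
0.5,0.82
1.0,0.87
2.0,0.90
5.0,0.93
10.0,0.95
20.0,0.96
50.0,0.97
100.0,0.98
500.0,0.99
1000.0,0.992
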