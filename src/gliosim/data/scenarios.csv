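index,khat0_d,rhohat0_d,Dw_mm2_per_d,Ie_lo,Ie_hi,Ic_lo,Ic_hi,khat1_d,rhohat1_d
1,14,21,0.015,0.012,0.03,0.16,0.80,18,27
2,35,35,0.030,0.016,0.04,0.22,0.40,37,27
3,56,49,0.060,0.024,0.06,0.30,0.50,58,27
4,56,49,0.030,0.016,0.04,0.16,0.80,18,57
5,14,21,0.060,0.024,0.06,0.22,0.40,37,57
6,35,35,0.015,0.012,0.03,0.30,0.50,58,57
7,56,35,0.060,0.012,0.03,0.22,0.40,18,97
8,14,49,0.015,0.016,0.04,0.30,0.50,37,97
9,35,21,0.030,0.024,0.06,0.16,0.80,58,97
10,14,35,0.030,0.024,0.06,0.30,0.50,18,27
11,35,49,0.060,0.012,0.03,0.16,0.80,37,27
12,56,21,0.015,0.016,0.04,0.22,0.40,58,27
13,35,49,0.015,0.024,0.06,0.22,0.40,18,57
14,56,21,0.030,0.012,0.03,0.30,0.50,37,57
15,14,35,0.060,0.016,0.04,0.16,0.80,58,57
16,35,21,0.060,0.016,0.04,0.30,0.50,18,97
17,56,35,0.015,0.024,0.06,0.16,0.80,37,97
18,14,49,0.030,0.012,0.03,0.22,0.40,58,97
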