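# soft tissue, ICRU-44 (density 1.060 g/cm3); energy keV, mu/rho cm2/g
10	5.270
15	1.660
20	0.8210
30	0.3780
40	0.2680
50	0.2260
60	0.2050
80	0.1820
100	0.1690
150	0.1490
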