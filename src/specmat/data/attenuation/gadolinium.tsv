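# gadolinium, elemental (density 7.900 g/cm3); K edge 50.2391 keV; energy keV, mu/rho cm2/g
10	180.0
15	61.00
20	27.90
30	9.300
40	4.310
50.2391	2.420
50.2392	12.10
60	7.900
80	3.950
100	2.280
150	0.8800
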