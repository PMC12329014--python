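# iodine, elemental (density 4.930 g/cm3); K edge 33.1694 keV; energy keV, mu/rho cm2/g
10	162.0
15	55.20
20	25.70
30	8.560
33.1694	6.550
33.1695	36.30
40	22.10
50	12.32
60	7.579
80	3.510
100	1.942
150	0.6978
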