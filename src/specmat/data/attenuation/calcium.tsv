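# calcium, elemental (density 1.550 g/cm3); energy keV, mu/rho cm2/g
10	93.41
15	29.66
20	13.06
30	4.080
40	1.830
50	1.019
60	0.6578
80	0.3656
100	0.2571
150	0.1672
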