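taxon	A	B	C	D	E	F
A	0	0.1625	0.225	0.1625	0.225	0.325
B	0.1625	0	0.25	0.1875	0.15	0.2625
C	0.225	0.25	0	0.0625	0.1375	0.275
D	0.1625	0.1875	0.0625	0	0.075	0.2125
E	0.225	0.15	0.1375	0.075	0	0.15
F	0.325	0.2625	0.275	0.2125	0.15	0
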