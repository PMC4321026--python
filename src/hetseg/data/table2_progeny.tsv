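genotype	normal	hs_exceptional	other	recombinant	paternal_ndj	decimals	correction
xxy	2076	40	0	0	0	1	derived
fm7_xxy	1356	1077	0	0	0	1	derived
in_dl49_xxy	1426	1371	28	25	3	1	derived
c1_c4	0	600	18	0	0	1	raw
c2l_c2r	0	2479	26	0	0	1	raw
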