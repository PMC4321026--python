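genotype	normal	hs_exceptional	other	recombinant	paternal_ndj	decimals	correction
c1_monovalent	182	1	0	0	0	0	derived
c4_monovalent	1136	0	6	0	6	0	derived
c4_inversion	626	9	1	1	0	1	derived
c4_balancer	1232	25	1	0	0	1	derived
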