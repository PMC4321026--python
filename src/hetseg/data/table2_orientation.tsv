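genotype	normal_orientation	hs_orientation	other_orientation
xxy	52	2	0
fm7_xxy	19	33	0
in_dl49_xxy	27	56	0
c1_c4	0	65	3
c2l_c2r	0	45	1
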