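genotype	stage	single_mass	one_plus_out	compound_out	hs_config	other_config
c1_monovalent	prometaphase_2d	32	40	23	0	0
c1_monovalent	metaphase_4d	112	9	0	2	0
c2en_monovalent	prometaphase_2d	29	60	28	0	0
c2en_monovalent	metaphase_4d	57	8	0	2	0
c4_monovalent	prometaphase_2d	72	2	2	0	0
c4_monovalent	metaphase_4d	60	0	0	2	0
c4_inversion	prometaphase_2d	54	7	7	0	0
c4_inversion	metaphase_4d	78	2	0	5	0
c4_balancer	prometaphase_2d	60	8	8	0	0
c4_balancer	metaphase_4d	70	2	0	5	0
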