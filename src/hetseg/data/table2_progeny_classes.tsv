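genotype	class_label	category	count
in_dl49_xxy	ywf_over_Y_sons	hs_exceptional	696
in_dl49_xxy	In1_yvf_over_yw_over_yplusY_daughters	hs_exceptional	675
in_dl49_xxy	yw_over_yplusY_sons	normal	367
in_dl49_xxy	In1_yvf_over_yplusY_sons	normal	350
in_dl49_xxy	yw_over_ywf_daughters	normal	352
in_dl49_xxy	In1_yvf_over_ywf_daughters	normal	357
in_dl49_xxy	rec_ywf_over_yplusY_sons	recombinant	6
in_dl49_xxy	rec_In1_yv_over_yplusY_sons	recombinant	10
in_dl49_xxy	rec_yv_over_ywf_daughters	recombinant	5
in_dl49_xxy	rec_ywf_over_ywf_daughters	recombinant	4
in_dl49_xxy	paternal_ndj_progeny	paternal_ndj	3
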