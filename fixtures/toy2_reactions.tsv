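id	name	equation	lower_bound	upper_bound	gpr	rtype	objective
EX_glc	glucose exchange	glc_e -->	-1000.0	1000		exchange	False
EX_nh4	ammonium exchange	nh4_e -->	-1000.0	1000		exchange	False
T_glc	glucose transport	glc_e --> glc_c	0.0	1000		transport	False
T_nh4	ammonium transport	nh4_e --> nh4_c	-1000.0	1000		transport	False
BIOMASS	biomass	glc_c + 0.1 hpo4_c + 0.5 nh4_c --> biomass_c	0.0	1000		biomass	True
ACALD_ASSIM	acetaldehyde assimilation (lumped)	3 acald_c + 3 h2o_c --> glc_c + 3 h2_c	0.0	1000		cytosolic	False
ALA_DEAM	L-alanine deamination (lumped)	ala__L_c + h2o_c + h_c --> 0.5 glc_c + nh4_c	0.0	1000		cytosolic	False
H2Ot	water transport	h2o_e --> h2o_c	-1000.0	1000		transport	False
Ht	proton transport	h_e --> h_c	-1000.0	1000		transport	False
H2t	hydrogen export	h2_c --> h2_e	0.0	1000		transport	False
CLt	chloride export	cl_c --> cl_e	0.0	1000		transport	False
HPO4t	phosphate transport	hpo4_e --> hpo4_c	0.0	1000		transport	False
EX_h2o		h2o_e -->	-1000.0	1000		exchange	False
EX_h		h_e -->	-1000.0	1000		exchange	False
EX_h2		h2_e -->	0.0	1000		exchange	False
EX_cl		cl_e -->	-1000.0	1000		exchange	False
EX_hpo4		hpo4_e -->	-1000.0	1000		exchange	False
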