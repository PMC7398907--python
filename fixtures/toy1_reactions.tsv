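id	name	equation	lower_bound	upper_bound	gpr	rtype	objective
EX_glc	glucose exchange	glc_e -->	-1000	1000		exchange	False
EX_nh4	ammonium exchange	nh4_e -->	-1000	1000		exchange	False
T_glc	glucose transport	glc_e --> glc_c	0	1000		transport	False
T_nh4	ammonium transport	nh4_e --> nh4_c	0	1000		transport	False
BIOMASS	biomass	glc_c + 0.5 nh4_c --> biomass_c	0	1000		biomass	True
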