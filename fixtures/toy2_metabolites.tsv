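id	name	formula	charge	compartment	boundary
glc_e	D-glucose	C6H12O6	0	e	False
glc_c	D-glucose	C6H12O6	0	c	False
nh4_e	ammonium	NH4	1	e	False
nh4_c	ammonium	NH4	1	c	False
biomass_c	biomass			c	True
acald_c	acetaldehyde	C2H4O	0	c	False
ala__L_c	L-alanine	C3H7NO2	0	c	False
h2o_e	water	H2O	0	e	False
h2o_c	water	H2O	0	c	False
h_e	proton	H	1	e	False
h_c	proton	H	1	c	False
h2_e	hydrogen	H2	0	e	False
h2_c	hydrogen	H2	0	c	False
cl_e	chloride	Cl	-1	e	False
cl_c	chloride	Cl	-1	c	False
hpo4_e	hydrogenphosphate	HPO4	-2	e	False
hpo4_c	hydrogenphosphate	HPO4	-2	c	False
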