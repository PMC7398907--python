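id	name	formula	charge	compartment	boundary
glc_e	D-glucose	C6H12O6	0	e	False
glc_c	D-glucose	C6H12O6	0	c	False
nh4_e	ammonium	NH4	1	e	False
nh4_c	ammonium	NH4	1	c	False
biomass_c	biomass			c	True
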