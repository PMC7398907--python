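exchange_id	max_uptake
EX_ca2	1000.0
EX_cl	1000.0
EX_co2	1000.0
EX_cu2	1000.0
EX_fe2	1000.0
EX_hpo4	1000.0
EX_k	1000.0
EX_mg2	1000.0
EX_mn2	1000.0
EX_so4	1000.0
EX_zn2	1000.0
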