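cn_ratio	cell_biomass_gDW_L	biomass_productivity_g_L_h	cordycepin_titer_g_L	cordycepin_productivity_g_L_h
7.3	20.315	0.423	1.288	0.027
9.7	19.544	0.407	1.366	0.028
11.6	18.019	0.375	1.521	0.032
14.6	16.635	0.347	1.416	0.029
19.4	14.097	0.294	1.35	0.028
29.1	12.373	0.258	1.133	0.024
58.2	9.619	0.2	0.95	0.02
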