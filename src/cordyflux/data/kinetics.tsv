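parameter	wild_type	producer
growth_rate_mu_max_h	0.032	0.025
biomass_production_gDW_L	8.690	5.860
sugar_uptake_mmol_gDW_h	0.632	0.549
cordycepin_production_mmol_gDW_h		0.013
cordycepin_yield_on_biomass_mg_gDW		81.975
cordycepin_titer_mg_L		479.970
in_silico_growth_rate_h	0.032	0.025
percent_error	0.94	2.77
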