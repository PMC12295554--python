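component	category	avg_mw	content	printed_coefficient
Proteins	protein	127.03	40.05	3.153
Chitin	carbohydrate	203.20	11.54	0.568
Glucan	carbohydrate	162.10	34.29	2.115
Glycogen	carbohydrate	666.60	0.16	0.002
RNA	nucleic_acid	495.30	5.16	0.104
DNA	nucleic_acid	482.73	0.78	0.016
Triacylglycerol	lipid	821.95	1.28	0.016
Phosphatidylcholine	lipid	744.76	0.15	0.002
Phosphatidylethanolamine	lipid	701.67	0.06	0.001
Palmitic acid (16:0)	lipid	200.32	0.17	0.009
Oleic acid (18:1 n-9)	lipid	242.40	0.15	0.006
Stearic acid (18:0)	lipid	239.20	0.33	0.014
Linoleic acid (18:2 n-6)	lipid	254.41	0.63	0.025
Arachidic acid (20:0)	lipid	265.30	0.01	0.0003
Sterol esters	lipid	302.45	0.48	0.016
Ergosterol	lipid	396.65	0.87	0.022
D-Mannitol	other	182.20	3.21	0.176
Glycerol	other	92.10	0.68	0.074
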