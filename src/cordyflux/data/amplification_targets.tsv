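ec_number	enzyme_name	gpr
1.2.1.46	Formaldehyde dehydrogenase	OAory_01014160 OAory_01017500 OAory_01018710
2.2.1.3	Formaldehyde transketolase	OAory_01025450 OAory_01077260 OAory_01105810
6.3.4.3	Formate tetrahydrofolate ligase	OAory_01002190
3.1.3.21	Glycerol-3-phosphate phosphohydrolase	OAory_01027100 OAory_01104250
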