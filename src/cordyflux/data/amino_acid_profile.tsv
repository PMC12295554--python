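amino_acid	content
L-Leucine	3.82
L-Arginine	3.27
L-Glutamate	2.81
L-Serine	2.72
L-Aspartate	2.53
L-Valine	2.33
L-Glycine	1.63
L-Asparagine	1.63
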