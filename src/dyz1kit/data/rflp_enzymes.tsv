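name	recognition	overhang	cut_top	cut_bottom
FspI	TGCGCA	blunt	3	3
MboI	GATC	5'	0	0
TaqI	TCGA	5'	1	1
AluI	AGCT	blunt	2	2
DraI	TTTAAA	blunt	3	3
AflIII	ACRYGT	5'	1	1
Sau3AI	GATC	5'	0	0
HhaI	GCGC	3'	3	3
EcoRV	GATATC	blunt	3	3
HaeIII	GGCC	blunt	2	2
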