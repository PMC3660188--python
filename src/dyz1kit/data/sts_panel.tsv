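sY_id	locus	multicopy
sY14	SRY exon 1	
sY1240	PCDH11Y intron 3	
sY276	AMELY exon 4/intron 4	
sY1238	TBL1Y exon 11	
sY637	PRKY 5' upstream of gene	
sY1319	PRKY 3' UTR	
sY1250	Proximal boundary of TSPY array	
sY78	Alpha satellite (DYZ3) sequences in centromeric region	*
sY1251	Boundary between centromere and Yq	
sY1317	USP9Y exon 3	
sY1316	USP9Y exon 26	
sY1234	DDX3Y (DBY) exon 9	
sY1231	UTY exon 8	
sY1235	XKRY exon 1	*
sY1260	CDY2 exon 1	*
sY1237	HSFY exon 2	*
sY121	Immediately distal to palindrome P4	
sY1322	Between CYorf15A & CYorf15B	
sY280	JARID1D (SMCY) exon 9/intron 9	
sY1233	EIF1AY exon 1	
sY1682	RPS4Y2 exon 1	
sY627	RBMY1 exon 12	*
sY1258	Boundary between unique sequence u1 & blue amplicon b1 in AZFc	
sY1161	PRY intron 2	*
sY1197	Internal boundary of Palindrome P3	
sY1191	Unique sequence u3 in AZFc	
sY1035	BPY2 intron 5	*
sY1318	DAZ exon 11	*
sY254	DAZ exon 3	*
sY1291	Red/gray boundary in AZFc	
sY1125	Blue/gray boundary in AZFc	*
sY1054	Blue/yellow boundary in AZFc	*
sY1190	Yellow amplicon in AZFc	*
sY1263	CDY1 exon 1/intron 1	*
sY1206	Yellow/green boundaries in AZFc	*
sY1201	Distal boundary of gray amplicon in AZFc	
sY1256	TSPY intron 5	*
sY1247	Boundary between PAR1 and MSY	
sY1230	TMSB4Y exon 1/intron 1	
sY1166	In MSY between distal Yq heterochromatin & PAR2	
sY274	RPS4Y1 intron 4	
sY1220	VCY exon 2	*
sY90	KALP intron 1	
sY210	STSP intron 5	
sY1254	TGIF2LY exon 1	
sY1239	NLGN4Y exon 1	
sY1273	Near boundary between MSY & PAR2	
sY238	ZFY intron 2	
sY1246	Proximal portion of distal Yq heterochromatin	
sY142	Proximal to AZFc	
sY160	Satellite-3 (DYZ1) sequences in distal Yq heterochromatin	*
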