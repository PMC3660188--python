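target	assay	sts_alias	accession	product_size	enzyme	fragments_allele_a	fragments_allele_b	du145	lncap
DAZ	DAZ-SNV_I		G73167	709	FspI	709	398+311	A&B	A&B
DAZ	DAZ-SNV_II		G73166	182	MboI	182	122+60	A&B	A&B
DAZ	DAZ-SNV_III	sY586	G63907	301	TaqI	301	184+117	A&B	A&B
DAZ	DAZ-SNV_IV		G73168	630	AluI	630	398+262	A&B	A&B
DAZ	DAZ-SNV_V	sY587	G63908	244	DraI	195+49	122+73+49	A&B	A&B
DAZ	DAZ-SNV_VI		G73169	431	AflIII	431	248+183	A&B	A
DAZ	DAZ-SNV_VII	sY581	G63906	252	Sau3AI	189+63	130+63+59	A&B	A&B
GOLY1	GOLY-SNV_1		BV012733	531	HhaI	531	289+282	A&B	A&B
BPY2	BPY2		BV012732	470	EcoRV	470	289+181	A&B	A
TTTY4	TTTY4		BV012731	541	HaeIII	541	323+218	A&B	A&B
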