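name	recognition	overhang	cut_top	cut_bottom
BsaBI	GATNNNNATC	blunt	5	5
Cac8I	GCNNGC	blunt	3	3
NlaIV	GGNNCC	blunt	3	3
BamHI	GGATCC	5'	1	1
BseYI	CCCAGC	5'	1	1
Bsp1407I	TGTACA	5'	1	1
BspHI	TCATGA	5'	1	1
ClaI	ATCGAT	5'	2	2
DdeI	CTNAG	5'	1	1
EcoRI	GAATTC	5'	1	1
EcoRII	CCWGG	5'	0	0
MaeII	ACGT	5'	1	1
MaeIII	GTNAC	5'	0	0
VspI	ATTAAT	5'	2	2
XhoII	RGATCY	5'	1	1
BseMII	CTCAG	3'		
BsgI	GTGCAG	3'		
BtsI	GCAGTG	3'		
Eco57I	CTGAAG	3'		
Eco57MI	CTGRAG	3'		
GsuI	CTGGAG	3'		
Hpy188I	TCNGA	3'	3	3
MnlI	CCTC	3'		
PflMI	CCANNNNNTGG	3'	7	7
SduI	GDGCHC	3'	5	5
ScrFI	CCNGG	5'	2	2
ArsI	GACNNNNNNTTYG	3'		
BdaI	TGANNNNNNTCA	3'		
CspCI	CAANNNNNGTGG	3'		
TspRI	CASTG	3'		
DpnI	GATC	blunt	2	2
ApoI	RAATTY	5'	1	1
AsuII	TTCGAA	5'	2	2
Eco31I	GGTCTC	5'		
MaeI	CTAG	5'	1	1
MboI	GATC	5'	0	0
SfaNI	GCATC	5'		
TatI	WGTACW	5'	1	1
SetI	ASST	3'		
CviJI	RGCY	blunt	2	2
MslI	CAYNNNNRTG	blunt	5	5
FokI	GGATG	5'		
AlfI	GCANNNNNNTGC	3'		
RsaI	GTAC	blunt	2	2
BccI	CCATC	5'		
BsmAI	GTCTC	5'		
MseI	TTAA	5'	1	1
BstXI	CCANNNNNNTGG	3'	8	8
MboII	GAAGA	3'		
XmnI	GAANNNNTTC	blunt	5	5
TstI	CACNNNNNNTCC	3'		
NlaIII	CATG	3'	4	4
BcgI	CGANNNNNNTGC	3'		
BsrDI	GCAATG	3'		
BsrI	ACTGG	3'		
TspGWI	ACGGA	3'		
AgsI	TTSAA	3'		
BsmI	GAATGC	3'		
FaiI	YATR	blunt	2	2
PleI	GAGTC	5'		
TspDTI	ATGAA	3'		
TspEI	AATT	5'	0	0
TfiI	GAWTC	5'	1	1
TaqI	TCGA	5'	1	1
HinfI	GANTC	5'	1	1
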