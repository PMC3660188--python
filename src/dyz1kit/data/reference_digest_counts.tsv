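name	AC068123.5	DU145	LNCaP
BsaBI	1	0	0
Cac8I	1	1	1
NlaIV	1	0	0
BamHI	1	0	0
BseYI	1	1	1
Bsp1407I	1	1	1
BspHI	1	1	1
ClaI	1	1	1
DdeI	1	1	1
EcoRI	1	1	1
EcoRII	1	0	0
MaeII	1	1	0
MaeIII	1	1	0
VspI	1	1	1
XhoII	1	0	0
BseMII	1	1	1
BsgI	1	1	1
BtsI	1	1	1
Eco57I	0	1	1
Eco57MI	1	2	2
GsuI	1	1	1
Hpy188I	1	1	1
MnlI	1	1	1
PflMI	1	1	1
SduI	1	1	1
ScrFI	2	1	1
ArsI	2	2	2
BdaI	2	2	2
CspCI	2	0	0
TspRI	2	2	2
DpnI	3	2	2
ApoI	3	3	3
AsuII	3	3	3
Eco31I	3	2	2
MaeI	3	3	4
MboI	3	2	2
SfaNI	3	4	4
TatI	3	3	3
SetI	3	3	1
CviJI	4	4	4
MslI	4	4	4
FokI	4	2	2
AlfI	4	4	4
RsaI	5	5	4
BccI	5	3	4
BsmAI	5	5	4
MseI	5	6	6
BstXI	5	5	4
MboII	5	3	3
XmnI	6	6	6
TstI	6	4	4
NlaIII	7	7	7
BcgI	16	14	14
BsrDI	16	14	14
BsrI	17	19	18
TspGWI	20	23	17
AgsI	22	20	23
BsmI	22	23	21
FaiI	23	25	23
PleI	23	21	21
TspDTI	25	24	24
TspEI	35	35	35
TfiI	52	51	51
TaqI	66	62	62
HinfI	75	72	72
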