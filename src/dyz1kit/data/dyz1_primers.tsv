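template	primer_id	sequence	length_bp	start	end	orientation	note
DYZ1	SAS 1	CCATTCGAGACCGTAGCAAT	20			5'-3'	binds 35-16 bases 5' upstream of the unit start (negative array coordinates)
DYZ1	SAS 2	TTTCCTTTCGCTTGCATTCCAT	22	63	84	5'-3'	
DYZ1	SAS 3	ATTTGATGCCATCCCATGAC	20	763	782	5'-3'	
DYZ1	SAS 4	TTTTGAGTCCGTTCCATAACAC	22	1380	1401	5'-3'	
DYZ1	SAS 5	TCCTTTGCCTTCCATTCG	18	1668	1685	5'-3'	
DYZ1	SAS 6	TGCAGTCTTTTCCCTTCGAG	20	2564	2583	5'-3'	
DYZ1	SAS 7	ATTGGATGGGATTGGAATGA	20	861	880	3'-5'	
DYZ1	SAS 8	TGGATGGACTGCAATAGAAAG	22	1600	1621	3'-5'	
DYZ1	SAS 9	TCGAATGGAAGGCAAAGG	18	1669	1686	3'-5'	
DYZ1	SAS 10	CGACTGGTACGGACTCCAAT	20	2637	2656	3'-5'	
DYZ1	SAS 11	GACTGGAAAGGCTGGGTGTCGA	22	3419	3440	3'-5'	
DYZ1	SAS 12	TGGACAGCCTGGAATAAAGTG	21	3586	3606	3'-5'	published 3' location; product sizes of every combination using this primer are consistent with a 3' end at 3571 instead
SRY	SA 531	GAATCTGGTAGAAGTGAGTTTTGGA	25	61	85	5'-3'	
SRY	SA 532	GCCTTTATTAGCCAGAGAAAAGAAA	25	860	884	3'-5'	
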