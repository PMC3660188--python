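combination	forward	reverse	amplicon_bp	annealing	extension
SAS (1&7)	SAS 1	SAS 7	915	64C-1.0'	72C-1.0'
SAS (1&8)	SAS 1	SAS 8	1656	65C-1.0'	72C-2.0'
SAS (1&9)	SAS 1	SAS 9	1721	61C-1.0'	72C-2.0'
SAS (2&7)	SAS 2	SAS 7	818	61C-1.0'	72C-1.0'
SAS (2&8)	SAS 2	SAS 8	1559	60C-1.0'	72C-1.5'
SAS (3&7)	SAS 3	SAS 7	118	55C-1.0'	72C-1.0'
SAS (3&8)	SAS 3	SAS 8	859	65C-1.0'	72C-1.0'
SAS (3&9)	SAS 3	SAS 9	924	61C-1.0'	72C-1.0'
SAS (3&10)	SAS 3	SAS 10	1894	64C-1.0'	72C-2.0'
SAS (4&8)	SAS 4	SAS 8	242	61C-1.0'	72C-1.0'
SAS (4&9)	SAS 4	SAS 9	307	55C-1.0'	72C-1.0'
SAS (4&10)	SAS 4	SAS 10	1277	61C-1.0'	72C-1.5'
SAS (4&11)	SAS 4	SAS 11	2061	62C-1.0'	72C-2.5'
SAS (4&12)	SAS 4	SAS 12	2192	61C-1.0'	72C-2.5'
SAS (5&10)	SAS 5	SAS 10	989	61C-1.0'	72C-1.0'
SAS (5&12)	SAS 5	SAS 12	1904	61C-1.0'	72C-2.0'
SAS (6&10)	SAS 6	SAS 10	93	61C-1.0'	72C-1.0'
SAS (6&11)	SAS 6	SAS 11	877	61C-1.0'	72C-1.0'
SAS (6&12)	SAS 6	SAS 12	1008	64C-1.0'	72C-1.0'
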