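label	AC068123.5	DU145	LNCaP
actual_size_bp	3564	3564	3465
TTCCA	229	235	228
1bp_derivatives	292	289	282
ATCCA	11	9	9
TACCA	3	3	2
TTACA	14	13	15
TTCAA	21	22	22
TTTCA	19	19	19
TTCTA	25	25	25
TTCCT	32	33	33
GTCCA	27	31	28
TGCCA	9	10	10
TTGCA	25	22	22
TTCGA	60	60	57
TTCCG	18	17	16
CTCCA	14	14	14
TCCCA	6	4	4
TTCCC	8	7	6
2bp_derivatives	142	142	139
3bp_derivatives	37	33	30
4bp_derivatives	9	9	10
5bp_derivatives	1	1	1
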