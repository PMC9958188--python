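residue_code	atom_name	type_id	mass	charge
A	P	0	30.9740	1.1662
A	OP1	1	15.9990	-0.7760
A	OP2	2	15.9990	-0.7760
A	O5'	3	15.9990	-0.4989
A	C5'	4	12.0110	0.0558
A	C4'	5	12.0110	0.1065
A	O4'	6	15.9990	-0.3548
A	C3'	7	12.0110	0.2022
A	O3'	8	15.9990	-0.5246
A	C2'	9	12.0110	0.0670
A	O2'	10	15.9990	-0.6139
A	C1'	11	12.0110	0.0394
A	N9	12	14.0070	-0.0251
A	C8	13	12.0110	0.2006
A	N7	14	14.0070	-0.6073
A	C5	15	12.0110	0.0515
A	C6	16	12.0110	0.7009
A	N6	17	14.0070	-0.9019
A	N1	18	14.0070	-0.7615
A	C2	19	12.0110	0.5875
A	N3	20	14.0070	-0.6997
A	C4	21	12.0110	0.3053
G	P	22	30.9740	1.1662
G	OP1	23	15.9990	-0.7760
G	OP2	24	15.9990	-0.7760
G	O5'	25	15.9990	-0.4989
G	C5'	26	12.0110	0.0558
G	C4'	27	12.0110	0.1065
G	O4'	28	15.9990	-0.3548
G	C3'	29	12.0110	0.2022
G	O3'	30	15.9990	-0.5246
G	C2'	31	12.0110	0.0670
G	O2'	32	15.9990	-0.6139
G	C1'	33	12.0110	0.0394
G	N9	34	14.0070	0.0492
G	C8	35	12.0110	0.1374
G	N7	36	14.0070	-0.5709
G	C5	37	12.0110	0.1744
G	C6	38	12.0110	0.4770
G	O6	39	15.9990	-0.5597
G	N1	40	14.0070	-0.4787
G	C2	41	12.0110	0.7657
G	N2	42	14.0070	-0.9672
G	N3	43	14.0070	-0.6323
G	C4	44	12.0110	0.1222
C	P	45	30.9740	1.1662
C	OP1	46	15.9990	-0.7760
C	OP2	47	15.9990	-0.7760
C	O5'	48	15.9990	-0.4989
C	C5'	49	12.0110	0.0558
C	C4'	50	12.0110	0.1065
C	O4'	51	15.9990	-0.3548
C	C3'	52	12.0110	0.2022
C	O3'	53	15.9990	-0.5246
C	C2'	54	12.0110	0.0670
C	O2'	55	15.9990	-0.6139
C	C1'	56	12.0110	0.0394
C	N1	57	14.0070	-0.0484
C	C2	58	12.0110	0.7538
C	O2	59	15.9990	-0.6252
C	N3	60	14.0070	-0.7584
C	C4	61	12.0110	0.8185
C	N4	62	14.0070	-0.9530
C	C5	63	12.0110	-0.5215
C	C6	64	12.0110	0.0053
U	P	65	30.9740	1.1662
U	OP1	66	15.9990	-0.7760
U	OP2	67	15.9990	-0.7760
U	O5'	68	15.9990	-0.4989
U	C5'	69	12.0110	0.0558
U	C4'	70	12.0110	0.1065
U	O4'	71	15.9990	-0.3548
U	C3'	72	12.0110	0.2022
U	O3'	73	15.9990	-0.5246
U	C2'	74	12.0110	0.0670
U	O2'	75	15.9990	-0.6139
U	C1'	76	12.0110	0.0394
U	N1	77	14.0070	0.0418
U	C2	78	12.0110	0.4687
U	O2	79	15.9990	-0.5477
U	N3	80	14.0070	-0.3549
U	C4	81	12.0110	0.5952
U	O4	82	15.9990	-0.5761
U	C5	83	12.0110	-0.3635
U	C6	84	12.0110	-0.1126
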