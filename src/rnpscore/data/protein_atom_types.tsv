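residue_code	atom_name	type_id	mass	charge
ALA	N	0	14.0070	-0.4157
ALA	CA	1	12.0110	0.0337
ALA	C	2	12.0110	0.5973
ALA	O	3	15.9990	-0.5679
ALA	CB	4	12.0110	0.0000
ARG	N	5	14.0070	-0.4157
ARG	CA	6	12.0110	0.0337
ARG	C	7	12.0110	0.5973
ARG	O	8	15.9990	-0.5679
ARG	CB	9	12.0110	0.0000
ARG	CG	10	12.0110	0.0000
ARG	CD	11	12.0110	0.0000
ARG	NE	12	14.0070	-0.5295
ARG	CZ	13	12.0110	0.8076
ARG	NH1	14	14.0070	-0.8627
ARG	NH2	15	14.0070	-0.8627
ASN	N	16	14.0070	-0.4157
ASN	CA	17	12.0110	0.0337
ASN	C	18	12.0110	0.5973
ASN	O	19	15.9990	-0.5679
ASN	CB	20	12.0110	0.0000
ASN	CG	21	12.0110	0.7130
ASN	OD1	22	15.9990	-0.5931
ASN	ND2	23	14.0070	-0.9191
ASP	N	24	14.0070	-0.4157
ASP	CA	25	12.0110	0.0337
ASP	C	26	12.0110	0.5973
ASP	O	27	15.9990	-0.5679
ASP	CB	28	12.0110	0.0000
ASP	CG	29	12.0110	0.7994
ASP	OD1	30	15.9990	-0.8014
ASP	OD2	31	15.9990	-0.8014
CYS	N	32	14.0070	-0.4157
CYS	CA	33	12.0110	0.0337
CYS	C	34	12.0110	0.5973
CYS	O	35	15.9990	-0.5679
CYS	CB	36	12.0110	0.0000
CYS	SG	37	32.0600	-0.3119
GLN	N	38	14.0070	-0.4157
GLN	CA	39	12.0110	0.0337
GLN	C	40	12.0110	0.5973
GLN	O	41	15.9990	-0.5679
GLN	CB	42	12.0110	0.0000
GLN	CG	43	12.0110	0.0000
GLN	CD	44	12.0110	0.6951
GLN	OE1	45	15.9990	-0.6086
GLN	NE2	46	14.0070	-0.9407
GLU	N	47	14.0070	-0.4157
GLU	CA	48	12.0110	0.0337
GLU	C	49	12.0110	0.5973
GLU	O	50	15.9990	-0.5679
GLU	CB	51	12.0110	0.0000
GLU	CG	52	12.0110	0.0000
GLU	CD	53	12.0110	0.8054
GLU	OE1	54	15.9990	-0.8188
GLU	OE2	55	15.9990	-0.8188
GLY	N	56	14.0070	-0.4157
GLY	CA	57	12.0110	0.0337
GLY	C	58	12.0110	0.5973
GLY	O	59	15.9990	-0.5679
HIS	N	60	14.0070	-0.4157
HIS	CA	61	12.0110	0.0337
HIS	C	62	12.0110	0.5973
HIS	O	63	15.9990	-0.5679
HIS	CB	64	12.0110	0.0000
HIS	CG	65	12.0110	0.0000
HIS	ND1	66	14.0070	-0.3811
HIS	CD2	67	12.0110	0.0000
HIS	CE1	68	12.0110	0.0000
HIS	NE2	69	14.0070	-0.5727
ILE	N	70	14.0070	-0.4157
ILE	CA	71	12.0110	0.0337
ILE	C	72	12.0110	0.5973
ILE	O	73	15.9990	-0.5679
ILE	CB	74	12.0110	0.0000
ILE	CG1	75	12.0110	0.0000
ILE	CG2	76	12.0110	0.0000
ILE	CD1	77	12.0110	0.0000
LEU	N	78	14.0070	-0.4157
LEU	CA	79	12.0110	0.0337
LEU	C	80	12.0110	0.5973
LEU	O	81	15.9990	-0.5679
LEU	CB	82	12.0110	0.0000
LEU	CG	83	12.0110	0.0000
LEU	CD1	84	12.0110	0.0000
LEU	CD2	85	12.0110	0.0000
LYS	N	86	14.0070	-0.4157
LYS	CA	87	12.0110	0.0337
LYS	C	88	12.0110	0.5973
LYS	O	89	15.9990	-0.5679
LYS	CB	90	12.0110	0.0000
LYS	CG	91	12.0110	0.0000
LYS	CD	92	12.0110	0.0000
LYS	CE	93	12.0110	0.0000
LYS	NZ	94	14.0070	-0.3854
MET	N	95	14.0070	-0.4157
MET	CA	96	12.0110	0.0337
MET	C	97	12.0110	0.5973
MET	O	98	15.9990	-0.5679
MET	CB	99	12.0110	0.0000
MET	CG	100	12.0110	0.0000
MET	SD	101	32.0600	-0.2737
MET	CE	102	12.0110	0.0000
PHE	N	103	14.0070	-0.4157
PHE	CA	104	12.0110	0.0337
PHE	C	105	12.0110	0.5973
PHE	O	106	15.9990	-0.5679
PHE	CB	107	12.0110	0.0000
PHE	CG	108	12.0110	0.0000
PHE	CD1	109	12.0110	0.0000
PHE	CD2	110	12.0110	0.0000
PHE	CE1	111	12.0110	0.0000
PHE	CE2	112	12.0110	0.0000
PHE	CZ	113	12.0110	0.0000
PRO	N	114	14.0070	-0.4157
PRO	CA	115	12.0110	0.0337
PRO	C	116	12.0110	0.5973
PRO	O	117	15.9990	-0.5679
PRO	CB	118	12.0110	0.0000
PRO	CG	119	12.0110	0.0000
PRO	CD	120	12.0110	0.0000
SER	N	121	14.0070	-0.4157
SER	CA	122	12.0110	0.0337
SER	C	123	12.0110	0.5973
SER	O	124	15.9990	-0.5679
SER	CB	125	12.0110	0.0000
SER	OG	126	15.9990	-0.6546
THR	N	127	14.0070	-0.4157
THR	CA	128	12.0110	0.0337
THR	C	129	12.0110	0.5973
THR	O	130	15.9990	-0.5679
THR	CB	131	12.0110	0.0000
THR	OG1	132	15.9990	-0.6761
THR	CG2	133	12.0110	0.0000
TRP	N	134	14.0070	-0.4157
TRP	CA	135	12.0110	0.0337
TRP	C	136	12.0110	0.5973
TRP	O	137	15.9990	-0.5679
TRP	CB	138	12.0110	0.0000
TRP	CG	139	12.0110	0.0000
TRP	CD1	140	12.0110	0.0000
TRP	CD2	141	12.0110	0.0000
TRP	NE1	142	14.0070	-0.3418
TRP	CE2	143	12.0110	0.0000
TRP	CE3	144	12.0110	0.0000
TRP	CZ2	145	12.0110	0.0000
TRP	CZ3	146	12.0110	0.0000
TRP	CH2	147	12.0110	0.0000
TYR	N	148	14.0070	-0.4157
TYR	CA	149	12.0110	0.0337
TYR	C	150	12.0110	0.5973
TYR	O	151	15.9990	-0.5679
TYR	CB	152	12.0110	0.0000
TYR	CG	153	12.0110	0.0000
TYR	CD1	154	12.0110	0.0000
TYR	CD2	155	12.0110	0.0000
TYR	CE1	156	12.0110	0.0000
TYR	CE2	157	12.0110	0.0000
TYR	CZ	158	12.0110	0.0000
TYR	OH	159	15.9990	-0.5579
VAL	N	160	14.0070	-0.4157
VAL	CA	161	12.0110	0.0337
VAL	C	162	12.0110	0.5973
VAL	O	163	15.9990	-0.5679
VAL	CB	164	12.0110	0.0000
VAL	CG1	165	12.0110	0.0000
VAL	CG2	166	12.0110	0.0000
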