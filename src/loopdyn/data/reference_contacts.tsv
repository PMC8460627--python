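state	res_a	num_a	res_b	num_b
HOLO	GLY	16	PRO	117
HOLO	GLY	16	THR	119
HOLO	ALA	20	SER	120
HOLO	ALA	20	MET	121
HOLO	THR	21	SER	120
HOLO	LYS	22	ASN	184'
HOLO	THR	26	GLY	15
HOLO	VAL	27	GLY	11
HOLO	VAL	27	THR	12
HOLO	VAL	27	GLY	15
HOLO	GLY	28	GLY	11
HOLO	GLY	28	ALA	14
HOLO	GLY	28	GLY	15
HOLO	VAL	32	GLY	50
HOLO	VAL	32	ALA	8
HOLO	THR	89	GLY	113
HOLO	GLY	17	THR	119
HOLO	GLY	17	ALA	38
HOLO	ASP	18	THR	119
HOLO	SER	19	THR	119
HOLO	ALA	20	THR	119
HOLO	THR	21	GLY	17'
HOLO	ASN	24	GLY	15
HOLO	ASN	24	ALA	282'
HOLO	ASN	24	GLU	283'
HOLO	TYR	25	GLY	16
HOLO	TYR	25	GLY	15
HOLO	TYR	25	GLY	17
HOLO	TYR	25	ALA	38
HOLO	THR	26	PRO	117
HOLO	VAL	27	ALA	14
HOLO	VAL	27	GLY	57
HOLO	VAL	27	ASN	34
HOLO	GLY	28	GLY	10
HOLO	GLY	28	THR	12
HOLO	GLY	28	ASN	55
HOLO	GLY	28	ILE	56
HOLO	LYS	29	ALA	14
HOLO	LYS	29	GLY	11
HOLO	LYS	29	GLY	15
HOLO	VAL	30	ALA	14
HOLO	VAL	30	GLY	11
HOLO	VAL	30	THR	12
HOLO	VAL	30	GLY	15
HOLO	GLY	31	GLY	10
HOLO	GLY	31	GLY	11
HOLO	GLY	31	THR	12
HOLO	VAL	32	GLY	11
HOLO	VAL	32	THR	12
HOLO	VAL	32	GLN	52
HOLO	THR	12	ALA	114
HOLO	THR	12	LEU	35
HOLO	THR	12	PRO	117
APO	GLY	16	PRO	117
APO	GLY	16	THR	119
APO	ALA	20	SER	120
APO	ALA	20	MET	121
APO	THR	21	SER	120
APO	LYS	22	ASN	184'
APO	THR	26	GLY	15
APO	VAL	27	GLY	11
APO	VAL	27	THR	12
APO	VAL	27	GLY	15
APO	GLY	28	GLY	11
APO	GLY	28	ALA	14
APO	GLY	28	GLY	15
APO	VAL	32	GLY	50
APO	VAL	32	ALA	8
APO	THR	89	GLY	113
APO	GLY	16	SER	118
APO	SER	19	SER	120
APO	SER	23	ARG	116
APO	SER	23	SER	120
APO	ASN	24	ARG	116
APO	TYR	25	MET	115
APO	TYR	25	ARG	116
APO	TYR	25	PRO	117
APO	THR	26	SER	118
APO	VAL	27	SER	118
APO	GLY	28	SER	118
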