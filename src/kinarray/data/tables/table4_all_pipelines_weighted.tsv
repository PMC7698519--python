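context	rank	kinase	family	printed	KRSA	UKA	PTMSEA	KEA3
PANC1	1	SRC	SRC	82	91	92	55	91
PANC1	2	FYN	SRC	81	91	88	68	78
PANC1	3	INSR	INSR	75	70	64	95	72
PANC1	4	ABL1	ABL	75	87	95	36	82
PANC1	5	LCK	SRC	71	91	100	9	85
PANC1	6	PDGFRA	PDGFR	70	83	91	9	97
PANC1	7	TXK	TEC	67	100	77	-	90
PANC1	8	RET	RET	67	26	77	77	87
PANC1	9	EPHA2	EPH	65	30	59	91	81
PANC1	10	SRMS	SRC	64	91	85	-	81
PDCL15	1	SRC	SRC	90	96	92	82	90
PDCL15	2	PDGFRA	PDGFR	86	87	93	68	97
PDCL15	3	INSR	INSR	73	70	57	100	65
PDCL15	4	LYN	SRC	72	96	99	59	34
PDCL15	5	PDGFRB	PDGFR	71	87	65	91	41
PDCL15	6	LCK	SRC	70	96	100	0	85
PDCL15	7	EPHA2	EPH	69	74	28	91	82
PDCL15	8	TXK	TEC	66	91	80	-	92
PDCL15	9	FYN	SRC	66	96	91	0	76
PDCL15	10	MST1R	MET	64	78	87	-	93
PDCL5	1	ALK	ALK	70	74	97	63	45
PDCL5	2	ZAP70	SYK	65	52	69	70	70
PDCL5	3	TXK	TEC	65	65	100	-	95
PDCL5	4	JAK2	JAK	65	43	91	53	73
PDCL5	5	EGFR	EGFR	62	83	58	67	42
PDCL5	6	KDR	VEGFR	62	91	39	30	89
PDCL5	7	EPHB3	EPH	62	61	88	-	98
PDCL5	8	AXL	AXL	59	57	28	97	54
PDCL5	9	CSK	CSK	59	13	72	87	63
PDCL5	10	INSR	INSR	58	78	23	70	61
Patient-Derived	1	LCK	SRC	80	96	88	60	78
Patient-Derived	2	SRC	SRC	79	96	45	96	81
Patient-Derived	3	LYN	SRC	72	96	96	64	32
Patient-Derived	4	PDGFRA	PDGFR	72	87	53	52	96
Patient-Derived	5	TXK	TEC	69	91	99	-	85
Patient-Derived	6	INSR	INSR	66	83	21	100	60
Patient-Derived	7	EGFR	EGFR	64	61	41	92	63
Patient-Derived	8	EPHA2	EPH	64	65	39	80	72
Patient-Derived	9	SRMS	SRC	63	96	79	-	76
Patient-Derived	10	EPHB3	EPH	58	65	75	-	93
All	1	SRC	SRC	85	91	76	91	82
All	2	LCK	SRC	81	91	99	55	78
All	3	PDGFRA	PDGFR	75	87	81	36	96
All	4	LYN	SRC	72	91	100	59	38
All	5	TXK	TEC	70	96	97	-	85
All	6	INSR	INSR	68	78	32	100	62
All	7	EPHA2	EPH	64	57	43	86	72
All	8	JAK2	JAK	64	61	68	64	63
All	9	SRMS	SRC	63	91	84	-	76
All	10	FYN	SRC	62	91	59	23	74
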