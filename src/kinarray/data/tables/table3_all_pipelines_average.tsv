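context	rank	kinase	family	printed	KRSA	UKA	PTMSEA	KEA3
PANC1	1	DDR2	DDR	97	96	-	-	98
PANC1	2	TXK	TEC	89	100	77	-	90
PANC1	3	SRMS	SRC	86	91	85	-	81
PANC1	4	SRC	SRC	82	91	92	55	91
PANC1	5	FYN	SRC	81	91	88	68	78
PANC1	6	MST1R	MET	76	35	97	-	95
PANC1	7	INSR	INSR	75	70	64	95	72
PANC1	8	ABL1	ABL	75	87	95	36	82
PANC1	9	FGR	SRC	73	91	83	-	45
PANC1	10	KIT	PDGFR	72	83	35	-	97
PDCL15	1	DDR2	DDR	99	100	-	-	98
PDCL15	2	SRC	SRC	90	96	92	82	90
PDCL15	3	PTK7	PTK7	88	-	88	-	-
PDCL15	4	TXK	TEC	88	91	80	-	92
PDCL15	5	PDGFRA	PDGFR	86	87	93	68	97
PDCL15	6	MST1R	MET	86	78	87	-	93
PDCL15	7	SRMS	SRC	84	96	73	-	82
PDCL15	8	KIT	PDGFR	78	87	49	-	97
PDCL15	9	INSR	INSR	73	70	57	100	65
PDCL15	10	TEC	TEC	72	91	97	-	28
PDCL5	1	PTK7	PTK7	99	-	99	-	-
PDCL5	2	ROS1	SEV	97	100	95	-	-
PDCL5	3	DDR2	DDR	92	87	-	-	97
PDCL5	4	TXK	TEC	87	65	100	-	95
PDCL5	5	EPHB3	EPH	82	61	88	-	98
PDCL5	6	LTK	ALK	80	74	86	-	-
PDCL5	7	EPHB1	EPH	76	61	92	-	76
PDCL5	8	FLT4	VEGFR	76	91	43	-	93
PDCL5	9	ITK	TEC	72	65	93	-	57
PDCL5	10	FLT1	VEGFR	72	91	65	-	59
Patient-Derived	1	PTK7	PTK7	100	-	100	-	-
Patient-Derived	2	DDR2	DDR	99	100	-	-	97
Patient-Derived	3	TXK	TEC	92	91	99	-	85
Patient-Derived	4	SRMS	SRC	84	96	79	-	76
Patient-Derived	5	LCK	SRC	80	96	88	60	78
Patient-Derived	6	ROS1	SEV	80	74	85	-	-
Patient-Derived	7	SRC	SRC	79	96	45	96	81
Patient-Derived	8	EPHB3	EPH	77	65	75	-	93
Patient-Derived	9	FLT3	PDGFR	74	87	36	-	99
Patient-Derived	10	ITK	TEC	74	91	80	-	50
All	1	DDR2	DDR	99	100	-	-	97
All	2	PTK7	PTK7	96	-	96	-	-
All	3	TXK	TEC	93	96	97	-	85
All	4	SRC	SRC	85	91	76	91	82
All	5	SRMS	SRC	84	91	84	-	76
All	6	LCK	SRC	81	91	99	55	78
All	7	PDGFRA	PDGFR	75	87	81	36	96
All	8	ROS1	SEV	74	70	79	-	-
All	9	FLT3	PDGFR	73	87	33	-	99
All	10	ITK	TEC	72	96	65	-	56
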