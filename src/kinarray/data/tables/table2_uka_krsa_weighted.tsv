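context	rank	kinase	family	printed	KRSA	UKA
PANC1	1	LCK	SRC	96	91	100
PANC1	2	LYN	SRC	95	91	99
PANC1	3	SRC	SRC	92	91	92
PANC1	4	ABL1	ABL	91	87	95
PANC1	5	TEC	TEC	90	100	80
PANC1	6	FYN	SRC	90	91	88
PANC1	7	BLK	SRC	89	91	87
PANC1	8	TXK	TEC	89	100	77
PANC1	9	SRMS	SRC	88	91	85
PANC1	10	ABL2	ABL	88	87	89
PDCL15	1	LCK	SRC	98	96	100
PDCL15	2	LYN	SRC	97	96	99
PDCL15	3	TEC	TEC	94	91	97
PDCL15	4	SRC	SRC	94	96	92
PDCL15	5	FYN	SRC	93	96	91
PDCL15	6	PDGFRA	PDGFR	90	87	93
PDCL15	7	FRK	FRK	89	83	96
PDCL15	8	BLK	SRC	88	96	81
PDCL15	9	HCK	SRC	86	96	77
PDCL15	10	TXK	TEC	86	91	80
PDCL5	1	ROS1	SEV	97	100	95
PDCL5	2	ALK	ALK	86	74	97
PDCL5	3	TXK	TEC	83	65	100
PDCL5	4	LTK	ALK	80	74	86
PDCL5	5	ITK	TEC	79	65	93
PDCL5	6	FLT1	VEGFR	78	91	65
PDCL5	7	EPHB1	EPH	76	61	92
PDCL5	8	EPHB3	EPH	74	61	88
PDCL5	9	BTK	TEC	72	65	78
PDCL5	10	EGFR	EGFR	70	83	58
Patient-Derived	1	LYN	SRC	96	96	96
Patient-Derived	2	TXK	TEC	95	91	99
Patient-Derived	3	TEC	TEC	94	91	97
Patient-Derived	4	LCK	SRC	92	96	88
Patient-Derived	5	BLK	SRC	91	96	87
Patient-Derived	6	SRMS	SRC	87	96	79
Patient-Derived	7	ITK	TEC	86	91	80
Patient-Derived	8	FRK	FRK	84	78	91
Patient-Derived	9	ROS1	SEV	80	74	85
Patient-Derived	10	HCK	SRC	78	96	60
All	1	TXK	TEC	96	96	97
All	2	LYN	SRC	96	91	100
All	3	LCK	SRC	95	91	99
All	4	TEC	TEC	93	96	91
All	5	BLK	SRC	90	91	88
All	6	SRMS	SRC	88	91	84
All	7	FRK	FRK	87	83	92
All	8	PDGFRA	PDGFR	84	87	81
All	9	SRC	SRC	84	91	76
All	10	ABL1	ABL	84	74	93
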