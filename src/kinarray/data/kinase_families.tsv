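kinase_id	family_id
ABL1	ABL
ABL2	ABL
ALK	ALK
AXL	AXL
BLK	SRC
BTK	TEC
CSK	CSK
DDR1	DDR
DDR2	DDR
EGFR	EGFR
EPHA2	EPH
EPHA8	EPH
EPHB1	EPH
EPHB3	EPH
FGR	SRC
FLT1	VEGFR
FLT3	PDGFR
FLT4	VEGFR
FRK	FRK
FYN	SRC
HCK	SRC
INSR	INSR
ITK	TEC
JAK2	JAK
KDR	VEGFR
KIT	PDGFR
LCK	SRC
LTK	ALK
LYN	SRC
MST1R	MET
PDGFRA	PDGFR
PDGFRB	PDGFR
PTK7	PTK7
RET	RET
ROS1	SEV
SRC	SRC
SRMS	SRC
TEC	TEC
TNK2	ACK
TXK	TEC
ZAP70	SYK
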