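gene	id	asd_lowiq	asd_normiq	sz	constrained	gradient
TCF4	LOF				X
ZEB2	LOF		missense		X	>
SMC1A	missense				X
SATB2	LOF				X
SOX2	LOF				X
CHD7	LOF	missense			X
RFX3	LOF			missense		>
HCFC1	missense				X
CUL3	LOF	LOF		missense	X	>
SALL1	LOF
MLL2	LOF				X
EHMT1	LOF
SOX5	LOF
KANSL1	LOF	missense
EP300	LOF			missense		>
TWIST1	LOF
KDM6A	LOF
NFIA	LOF	LOF
SKI	missense
NFIX	LOF				X
SMAD4	missense	missense
ARID1A	LOF
SMARCE1	missense
SMARCB1	missense				X
SMARCA4	missense				X
CUL4B	LOF
ADNP		LOF 2x
AHDC1		LOF, missense		missense	X	>
SETD2		LOF	missense			>
TBL1XR1		LOF, missense
UBAP2L		LOF			X
UBR5			LOF	missense	X
BRCA1			LOF
CNOT3		LOF			X
ILF2		LOF
NFIB		LOF
CDC23		LOF
NACC1		LOF			X
SOX6		missense
ZNF219		missense			X
TRRAP		missense 2x	missense	missense	X
CHD4		missense			X
EP400			missense		X
NCOR1		missense			X
NR2F1			missense		X
ZHX3		missense
ZNF462			missense		X
KDM1A		missense			X
RUVBL1			missense
HDAC1		missense
MBD2			missense
CNOT1		missense			X
RCOR2		missense
SMC3			missense		X
TCF3			missense
ETV6		missense
ZEB1				LOF
SMARCC2				LOF	X
ANAPC5				missense
WIZ				missense	X
KDM3B				missense	X
ZFR				missense
MAML2				missense
QSER1				missense
RIF1				missense
NCOR2				missense
ZBTB45				missense	X
PBX1				missense
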