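gene	direction	statistic
CYP1B1	up	<0.0001
KLF12	up	<0.0001
PRSS35	up	<0.001
GLS2	down	<0.001
ENPP4	up	<0.001
ZMAT1	up	<0.001
TMEM184C	up	<0.001
ADAM12	up	<0.001
RAB11FIP1	up	<0.001
PTGER2	up	<0.001
SERPINB2	up	<0.001
SCFD2	up	<0.01
KRTAP4-8	up	<0.01
C10orf136	up	<0.01
HES1	down	<0.01
COL1A2	up	<0.01
HIST1H2BJ	up	<0.01
RBPJL	up	<0.01
CRTAC1	down	<0.01
CCDC148	down	<0.01
ROR1	up	<0.01
EDN1	down	<0.01
TGFB2	up	<0.01
PRKCZ	up	<0.01
MARVELD2	up	<0.01
ATF3	down	<0.01
CD82	down	<0.01
XTP3TPA	up	<0.01
SPTAN1	down	<0.01
KIAA1655	up	<0.01
DDB2	down	<0.01
SNAI1	down	<0.01
STC2	up	<0.01
TNC	up	<0.01
LRRIQ1	down	<0.01
ASMT	up	<0.01
GATA6	up	<0.01
GDF-15	down	<0.01
PCDHGA3	down	<0.01
DDX19A	up	<0.01
RARB	up	<0.01
CCND2	down	<0.01
BCS1L	up	<0.01
BIRC7	up	<0.01
MX1	down	<0.01
RERG	up	<0.01
ADAMTS12	up	<0.01
DUSP1	down	<0.01
AREG	down	<0.01
OSBPL1A	up	<0.01
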