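gene	direction	statistic
MX1	down	<0.0001
GPR87	down	<0.0001
IFI27	down	<0.0001
JMJD4	up	<0.001
FAM155A	down	<0.001
OAS3	down	<0.001
MX2	down	<0.001
HLA-F	down	<0.001
AREG	down	<0.001
LOC158376	up	<0.001
ALKBH8	up	<0.001
ABCC4	up	<0.001
HIST2H2BE	down	<0.001
RFT1	up	<0.001
LRRC38	up	<0.001
SNAI1	down	<0.001
C19orf42	up	<0.01
LOC151171	down	<0.01
SIAE	down	<0.01
IQGAP2	down	<0.01
POLA1	up	<0.01
PDK4	down	<0.01
ATF3	down	<0.01
TNFSF10	down	<0.01
DHX37	up	<0.01
TOMM40L	up	<0.01
IFIT3	down	<0.01
IFI44L	down	<0.01
TNC	up	<0.01
KREMEN2	down	<0.01
HNMT	down	<0.01
BRD9	up	<0.01
BEX2	down	<0.01
MGC33894	down	<0.01
DUSP1	down	<0.01
C7orf54	down	<0.01
ID4	up	<0.01
CCDC148	down	<0.01
MDM2	down	<0.01
PRAP1	down	<0.01
FOS	down	<0.01
HES1	down	<0.01
ASPA	down	<0.01
GDF-15	down	<0.01
COL9A3	down	<0.01
LGALS9	down	<0.01
NR4A1	down	<0.01
ADAM12	up	<0.01
RNASE7	down	<0.01
HHATL	down	<0.01
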