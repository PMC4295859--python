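gene	direction	statistic
ATF3	up	9.574
KIAA1370	up	9.574
RRAD	up	9.552
C12orf5	up	9.476
GDF-15	up	9.454
GPR87	up	9.454
MDM2	up	9.356
SESN2	up	9.258
COL7A1	up	9.16
ATG16L2	up	9.16
AK1	up	9.16
FAS	up	8.964
LIF	up	8.964
VWCE	up	8.866
TP53INP1	up	8.817
VDR	up	8.811
C4orf18	up	8.768
FERMT1	up	8.734
FUCA1	up	8.691
MCC	up	8.691
NELF	up	8.691
BTG2	up	8.691
TGFBR1	up	8.691
TMEM131	up	8.572
CDH10	up	8.572
FZD2	down	-7.775
C3orf36	down	-7.809
TRIB2	down	-7.817
SMA5	down	-7.835
NDRG4	down	-7.869
EBPL	down	-7.873
TGFB2	down	-7.912
MYCN	down	-7.971
SEMA3A	down	-7.971
GIMAP2	down	-7.992
ZFP36	down	-8.001
UBE2G2	down	-8.044
RNASE1	down	-8.069
MXD3	down	-8.21
HIST1H2AM	down	-8.218
C14orf94	down	-8.222
PIF1	down	-8.261
OASL	down	-8.265
PRSS35	down	-8.44
CLEC14A	down	-8.482
HOXD8	down	-8.679
HIST1H1D	down	-8.713
CLEC3B	down	-8.866
VCAM1	down	-9.16
C9orf3	down	-9.552
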