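gene	direction	statistic
CORT	up	9.577
TREM2	up	9.222
ATF3	up	9.039
AVPI1	up	8.757
AK1	up	8.658
VASN	up	8.653
SESN2	up	8.633
LRDD	up	8.633
AREG	up	8.633
PLCD1	up	8.586
ADM	up	8.549
LRRTM2	up	8.524
DEDD2	up	8.457
RALGDS	up	8.37
DNAJB2	up	8.364
MSX1	up	8.328
MST150	up	8.322
NR4A3	up	8.157
FDXR	up	8.143
ITPKA	up	8.143
KREMEN2	up	8.143
SLC31A2	up	8.126
CEACAM1	up	8.107
IRF5	up	8.101
FOXL2	up	8.101
VCAM1	down	-8.432
C7orf10	down	-8.437
C3orf26	down	-8.438
MYRIP	down	-8.535
ROR1	down	-8.56
QKI	down	-8.597
TRIB2	down	-8.628
CDKAL1	down	-8.647
TFPI	down	-8.658
LTBP1	down	-8.664
PLK1	down	-8.686
NAV1	down	-8.714
PAPPA	down	-8.726
PIF1	down	-8.765
DHRSX	down	-8.891
GMDS	down	-8.928
LAMA4	down	-9.02
DKFZP0335	down	-9.02
CD9	down	-9.051
FAT4	down	-9.124
DOCK1	down	-9.222
SMAD7	down	-9.32
FHOD3	down	-9.381
CLEC14A	down	-9.418
SEMA3A	down	-9.418
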