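symbol
SEPT1
SEPT2
SEPT3
SEPT4
SEPT5
SEPT6
SEPT7
SEPT8
SEPT9
SEPT10
SEPT11
SEPT12
SEPT14
SEP15
MARCH1
MARCH2
MARCH3
MARCH4
MARCH5
MARCH6
MARCH7
MARCH8
MARCH9
MARCH10
MARCH11
DEC1
DEC2
OCT4
MEI1
AGO2
TAMM41
ELO2
2310009E13
1110059E24
2610019E17
TP53
NCF1
BRCA1
BRCA2
EGFR
KRAS
NRAS
MYC
MYCN
GAPDH
ACTB
VEGFA
IL6
TNF
CDKN2A
PTEN
FOXP2
SOX2
NANOG
PAX6
HOXA1
GATA4
RUNX1
NOTCH1
WNT5A
SHH
BMP4
FGF2
PDGFRA
ALK
RET
MET
KIT
FLT3
JAK2
STAT3
NFKB1
RELA
MAPK1
AKT1
PIK3CA
MTOR
RB1
ATM
CHEK2
MDM2
CCND1
CDK4
ERBB2
ESR1
PGR
AR
JUN
FOS
TGFB1
SMAD4
CTNNB1
APC
VHL
NF1
TSC1
TSC2
BCL2
BAX
CASP3
TERT
POLD1
POLE
MSH2
MLH1
PMS2
XRCC1
ATR
BRIP1
PALB2
RAD51
FANCA
ERCC1
XPC
LIG4
PRKDC
TREX1
CGAS
STING1
IFNB1
IRF3
TLR4
CD4
CD8A
CD19
MS4A1
PDCD1
CD274
CTLA4
LAG3
HAVCR2
FOXP3
IL2RA
GZMB
PRF1
KLRD1
NCAM1
ITGAM
ITGAX
CSF1R
CX3CR1
CCR2
CCL2
CXCL10
CXCR4
SELL
ICAM1
VCAM1
PECAM1
CDH1
CDH2
VIM
FN1
COL1A1
MMP2
MMP9
TIMP1
SNAI1
SNAI2
TWIST1
ZEB1
ZEB2
KLF4
POU5F1
LIN28A
DNMT1
DNMT3A
DNMT3B
TET2
IDH1
IDH2
EZH2
KMT2A
KDM6A
ARID1A
SMARCA4
BRD4
HDAC1
SIRT1
EP300
CREBBP
TAF1
POLR2A
XRN1
DIS3
EXOSC10
UPF1
EIF4E
RPS6
RPL13A
MRPL11
TUFM
HSPA5
HSP90AA1
DNAJB1
BAG3
SQSTM1
MAP1LC3B
ATG5
ATG7
BECN1
LAMP1
CTSB
GBA1
SMPD1
NPC1
ABCA1
LDLR
PCSK9
APOB
APOE
LPL
CETP
SCARB1
SREBF1
HMGCR
FASN
ACACA
SCD
CPT1A
ACOX1
PPARA
PPARG
PPARGC1A
NR1H3
RXRA
THRB
ESRRA
HNF4A
FOXO1
FOXA2
PDX1
INS
GCG
SST
IAPP
SLC2A2
GCK
KCNJ11
ABCC8
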