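# cardiotriage panel catalog, schema panel-catalog/1.0
# gene<TAB>known association tags (DCM/HCM/ARVC/channelopathy), comma-separated
MYH7	DCM,HCM
MYBPC3	DCM,HCM
TNNT2	DCM,HCM
TNNI3	DCM,HCM
TPM1	DCM,HCM
MYL2	HCM
MYL3	HCM
ACTC1	DCM,HCM
TNNC1	DCM,HCM
MYH6	DCM,HCM
MYLK2	HCM
TTN	DCM,HCM,ARVC
MYOM1	HCM
LMNA	DCM
DES	DCM,ARVC
SCN5A	DCM,channelopathy
BAG3	DCM
RBM20	DCM
PLN	DCM,HCM,ARVC
TCAP	DCM,HCM
CSRP3	DCM,HCM
ACTN2	DCM,HCM
LDB3	DCM,ARVC
VCL	DCM,HCM
NEXN	DCM,HCM
ANKRD1	DCM,HCM
TMPO	DCM
PSEN1	DCM
PSEN2	DCM
EYA4	DCM
SGCD	DCM
CTF1	DCM
ABCC9	DCM
TAZ	DCM
DMD	DCM
EMD	DCM
FKTN	DCM
DOLK	DCM
GATAD1	DCM
LAMA4	DCM
ILK	DCM
MYPN	DCM,HCM
PDLIM3	DCM
NEBL	DCM
CRYAB	DCM
FHL2	DCM
SYNE1	DCM
SYNE2	DCM
PRDM16	DCM
TBX20	DCM
GATA4	DCM
NKX2-5	DCM,channelopathy
OBSCN	DCM,HCM
TTR	HCM
FHL1	HCM
GLA	HCM
LAMP2	HCM
PRKAG2	HCM
JPH2	HCM
CALR3	HCM
MYOZ2	HCM
CAV3	HCM,channelopathy
FLNC	DCM,HCM,ARVC
RAF1	HCM
PTPN11	HCM
MYO6	DCM,HCM
CHRM2	DCM,HCM
PKP2	ARVC
DSP	DCM,ARVC
DSG2	DCM,ARVC
DSC2	ARVC
JUP	ARVC
TMEM43	ARVC
DTNA	ARVC
TGFB3	ARVC
CTNNA3	ARVC
PKP4	ARVC
RYR2	ARVC,channelopathy
KCNQ1	channelopathy
KCNH2	channelopathy
KCNE1	channelopathy
KCNE2	channelopathy
KCNE3	channelopathy
KCNJ2	channelopathy
KCNJ5	channelopathy
KCNJ8	channelopathy
SCN1B	channelopathy
SCN2B	channelopathy
SCN3B	channelopathy
SCN4B	channelopathy
SCN10A	channelopathy
CACNA1C	channelopathy
CACNB2	channelopathy
CACNA2D1	channelopathy
HCN4	channelopathy
ANK2	channelopathy
AKAP9	channelopathy
SNTA1	channelopathy
TRDN	channelopathy
CASQ2	channelopathy
CALM1	channelopathy
CALM2	channelopathy
CALM3	channelopathy
TRPM4	channelopathy
GPD1L	channelopathy
KCND3	channelopathy
KCNA5	channelopathy
NUP155	channelopathy
DLG1	channelopathy
RANGRF	channelopathy
KCND2	channelopathy
GJA5	channelopathy
TNNI3K	DCM
LRRC10	DCM
SLC25A4	DCM
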