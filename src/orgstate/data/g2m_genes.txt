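HMGB2
CDK1
NUSAP1
UBE2C
BIRC5
TPX2
TOP2A
NDC80
CKS2
NUF2
CKS1B
MKI67
TMPO
CENPF
TACC3
FAM64A
SMC4
CCNB2
CKAP2L
CKAP2
AURKB
BUB1
KIF11
ANP32E
TUBB4B
GTSE1
KIF20B
HJURP
CDCA3
HN1
CDC20
TTK
CDC25C
KIF2C
RANGAP1
NCAPD2
DLGAP5
CDCA2
CDCA8
ECT2
KIF23
HMMR
AURKA
PSRC1
ANLN
LBR
CKAP5
CENPE
CTCF
NEK2
G2E3
GAS2L3
CBX5
CENPA
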