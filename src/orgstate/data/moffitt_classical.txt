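BTNL8
FAM3D
PRR15L
AGR3
CTSE
LYZ
TFF2
TFF1
ANXA10
LGALS4
PLA2G10
CEACAM6
VSIG2
TSPAN8
ST6GALNAC1
AGR2
TFF3
SPINK4
MYO1A
CLRN3
KRT20
CDH17
REG4
FAM83E
GPX2
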