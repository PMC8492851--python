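VGLL1
UCA1
S100A2
LY6D
SPRR3
SPRR1B
LEMD1
KRT15
CTGF
ANXA8L2
DHRS9
AREG
CST6
SERPINB3
KRT6C
KRT6A
SERPINB4
FAM83A
SCEL
FGFBP1
KRT7
KRT17
GPR87
TNS4
SLC2A1
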