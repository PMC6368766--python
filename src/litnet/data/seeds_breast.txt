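RAD54L
CASP8
BARD1
PIK3CA
HMMR
NQO2
ESR1
RB1CC1
SLC22A1L
TSG101
ATM
KRAS
BRCA2
XRCC3
AKT1
RAD51A
PALB2
TP53
PHB
PPM1D
BRIP1
CHEK2
CDH1
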