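TNF
EGFR
CRC
PTEN
IL-6
AR
BRCA1
EGF
GAPDH
HR
AML
CD4
STAT3
AD
MMP-9
MS
RD
MYC
S6
TP53
ATM
IL-8
AP1
MMP-2
GC
FBS
ES
RA
CXCR4
BRCA2
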