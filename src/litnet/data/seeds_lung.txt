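FASLG
CASP8
DLEC1
RASSF1
PIK3CA
IRF1
PRKN
EGFR
BRAF
MAP3K8
ERCC6
SLC22A1L
PPP2R1B
KRAS
ERBB2
CYP2A6
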