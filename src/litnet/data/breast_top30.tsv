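gene	status
BRCA2	YES+Seed
ESR1	YES+Seed
CDH1	YES+Seed
BRCA1	YES
PPM1D	YES+Seed
NQO2	YES+Seed
XRCC3	YES+Seed
TSG101	YES+Seed
CDKN2A	candidate
PALB2	YES+Seed
BRIP1	YES+Seed
PIK3CA	YES+Seed
MRE11A	candidate
RAD54L	YES+Seed
ERBB2	YES
CHEK2	YES+Seed
RAD51C	candidate
AKT1	YES+Seed
TP53	YES+Seed
RB1CC1	YES+Seed
RB1	YES
HMMR	YES+Seed
STK11	YES
BARD1	YES+Seed
RAD51	YES
KRAS	YES+Seed
RAD50	candidate
ATM	YES+Seed
BACH1	Seed
CASP8	YES+Seed
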