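PCAP
HPC5
MAD1L1
HPC4
HIP1
MSR1
KLF6
PTEN
MXI1
CD82
BRCA2
CDH1
ZFHX3
HPCQTL19
HPC3
CHEK2
HPC6
AR
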