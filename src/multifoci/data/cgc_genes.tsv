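gene
TP53
BRCA1
BRCA2
ATM
MLH1
MSH2
PALB2
CHEK2
APC
CDH1
CTNNB1
CDKN2A
RB1
KRAS
PIK3CA
EGFR
ERBB2
BRAF
MET
NOTCH1
NOTCH2
SMAD4
PTEN
ARID1A
KMT2D
CCND1
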