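gene	category
HLA-A	immune
HLA-B	immune
B2M	immune
IL7R	immune
TLR4	immune
CD8A	immune
IFNGR1	immune
JAK3	immune
STAT1	immune
TNF	immune
IL2RA	immune
CXCR4	immune
CDKN2A	cell_cycle
CDKN2B	cell_cycle
CCND1	cell_cycle
RB1	cell_cycle
CDK4	cell_cycle
CCNE1	cell_cycle
CDK6	cell_cycle
E2F1	cell_cycle
EGFR	proliferation
KRAS	proliferation
MYC	proliferation
PIK3CA	proliferation
ERBB2	proliferation
BRAF	proliferation
FGFR1	proliferation
MET	proliferation
BRCA1	dna_repair
BRCA2	dna_repair
ATM	dna_repair
MLH1	dna_repair
MSH2	dna_repair
PALB2	dna_repair
RAD51	dna_repair
CHEK2	dna_repair
CDH1	adhesion
CTNNB1	adhesion
FAT2	adhesion
PCDH15	adhesion
ITGA6	adhesion
LAMA3	adhesion
COL11A1	adhesion
DSG3	adhesion
TP53	other
MUC16	other
DGKZ	other
APC	other
NOTCH1	other
NOTCH2	other
NOTCH3	other
NOTCH4	other
CTTN	other
KMT2D	other
ARID1A	other
NFE2L2	other
ZNF750	other
SMAD4	other
PTEN	other
OR2T4	other
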