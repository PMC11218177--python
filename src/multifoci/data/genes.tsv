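gene	contig	start	end
HLA-A	chr1	2000000	2100000
HLA-B	chr1	6000000	6100000
B2M	chr1	10000000	10100000
IL7R	chr1	14000000	14100000
TLR4	chr1	18000000	18100000
CD8A	chr1	22000000	22100000
IFNGR1	chr1	26000000	26100000
JAK3	chr1	30000000	30100000
STAT1	chr1	34000000	34100000
TNF	chr1	38000000	38100000
IL2RA	chr1	42000000	42100000
CXCR4	chr1	46000000	46100000
CDKN2A	chr2	2000000	2100000
CDKN2B	chr2	6000000	6100000
CCND1	chr2	10000000	10100000
RB1	chr2	14000000	14100000
CDK4	chr2	18000000	18100000
CCNE1	chr2	22000000	22100000
CDK6	chr2	26000000	26100000
E2F1	chr2	30000000	30100000
EGFR	chr2	34000000	34100000
KRAS	chr2	38000000	38100000
MYC	chr2	42000000	42100000
PIK3CA	chr2	46000000	46100000
ERBB2	chr3	2000000	2100000
BRAF	chr3	6000000	6100000
FGFR1	chr3	10000000	10100000
MET	chr3	14000000	14100000
BRCA1	chr3	18000000	18100000
BRCA2	chr3	22000000	22100000
ATM	chr3	26000000	26100000
MLH1	chr3	30000000	30100000
MSH2	chr3	34000000	34100000
PALB2	chr3	38000000	38100000
RAD51	chr3	42000000	42100000
CHEK2	chr3	46000000	46100000
CDH1	chr4	2000000	2100000
CTNNB1	chr4	6000000	6100000
FAT2	chr4	10000000	10100000
PCDH15	chr4	14000000	14100000
ITGA6	chr4	18000000	18100000
LAMA3	chr4	22000000	22100000
COL11A1	chr4	26000000	26100000
DSG3	chr4	30000000	30100000
TP53	chr4	34000000	34100000
MUC16	chr4	38000000	38100000
DGKZ	chr4	42000000	42100000
APC	chr4	46000000	46100000
NOTCH1	chr5	2000000	2100000
NOTCH2	chr5	6000000	6100000
NOTCH3	chr5	10000000	10100000
NOTCH4	chr5	14000000	14100000
CTTN	chr5	18000000	18100000
KMT2D	chr5	22000000	22100000
ARID1A	chr5	26000000	26100000
NFE2L2	chr5	30000000	30100000
ZNF750	chr5	34000000	34100000
SMAD4	chr5	38000000	38100000
PTEN	chr5	42000000	42100000
OR2T4	chr5	46000000	46100000
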