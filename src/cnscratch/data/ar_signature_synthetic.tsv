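# Synthetic stand-in androgen-response signature (27 genes, 20 up / 7 down).
# Gene symbols are canonical androgen-regulated genes; the exact published
# 27-gene response list is not redistributed here, so this default is a
# constructed stand-in intended for the bundled simulator. Replace with your
# own two-column TSV (gene, direction) for real data.
gene	direction
KLK3	up
KLK2	up
TMPRSS2	up
NKX3-1	up
FKBP5	up
PMEPA1	up
SLC45A3	up
NDRG1	up
PART1	up
STEAP1	up
STEAP2	up
ACSL3	up
ELL2	up
GNMT	up
HERC3	up
PTGER4	up
ABCC4	up
ADAM7	up
EAF2	up
MED28	up
SERPINI1	down
OPRK1	down
DDC	down
TNK1	down
GREB1	down
CDK8	down
MYC	down
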