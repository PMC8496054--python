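# Default CIN25 signature gene list (editable).
# The first seven symbols are canonical chromosomal-instability genes;
# the CIN_GENE_* entries are placeholders — replace them with your full
# 25-gene list (one symbol per line) before scoring real cohorts.
AURKA
AURKB
CCNB1
CCNB2
FOXM1
TOP2A
TTK
CIN_GENE_08
CIN_GENE_09
CIN_GENE_10
CIN_GENE_11
CIN_GENE_12
CIN_GENE_13
CIN_GENE_14
CIN_GENE_15
CIN_GENE_16
CIN_GENE_17
CIN_GENE_18
CIN_GENE_19
CIN_GENE_20
CIN_GENE_21
CIN_GENE_22
CIN_GENE_23
CIN_GENE_24
CIN_GENE_25
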