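# Immune-specific marker genes used for the per-sample immune content score.
# Curated stand-in list of canonical lineage and effector markers spanning
# T, B, NK and myeloid compartments plus antigen presentation; replaceable
# by any user-supplied one-symbol-per-line file.
PTPRC
CD2
CD3D
CD3E
CD3G
CD4
CD8A
CD8B
IL7R
CCR7
CD27
CD28
ICOS
CTLA4
PDCD1
LAG3
TIGIT
HAVCR2
FOXP3
IL2RA
IL2RB
CD19
MS4A1
CD79A
CD79B
BLK
BANK1
TNFRSF17
NKG7
GNLY
KLRD1
KLRB1
KLRK1
NCR1
GZMA
GZMB
GZMK
PRF1
EOMES
TBX21
CD14
CD68
CD163
CSF1R
FCGR3A
FCGR2A
ITGAM
ITGAX
LYZ
AIF1
MNDA
MRC1
MSR1
CXCR3
CCR5
CXCL9
CXCL10
CCL5
IFNG
STAT1
HLA-DRA
HLA-DRB1
HLA-DPA1
HLA-DPB1
HLA-DQA1
B2M
TAP1
TAPBP
CD74
CIITA
TRAC
TRBC1
IGHM
IGKC
SLAMF7
CD40LG
TNFRSF9
GZMH
CTSW
CST7
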