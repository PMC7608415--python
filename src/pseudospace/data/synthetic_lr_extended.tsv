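ligand	receptor	weight
TGFB1	TGFBR1	1
TGFB1	TGFBR2	1
TGFB2	TGFBR1	1
TGFB2	TGFBR2	1
TGFB3	TGFBR1	1
TGFB3	TGFBR2	1
CCL5	CCR5	1
CCL5	CCR1	1
CCL5	CCR3	1
CCL4	CCR5	1
CCL4	CCR8	1
CCL3	CCR1	1
CCL3	CCR5	1
CCL2	CCR2	1
CCL19	CCR7	1
CCL21	CCR7	1
CXCL9	CXCR3	1
CXCL10	CXCR3	1
CXCL11	CXCR3	1
CXCL12	CXCR4	1
CXCL13	CXCR5	1
CX3CL1	CX3CR1	1
IL2	IL2RA	1
IL2	IL2RB	1
IL2	IL2RG	1
IL4	IL4R	1
IL4	IL2RG	1
IL6	IL6R	1
IL6	IL6ST	1
IL7	IL7R	1
IL7	IL2RG	1
IL10	IL10RA	1
IL10	IL10RB	1
IL12A	IL12RB1	1
IL12B	IL12RB2	1
IL15	IL15RA	1
IL15	IL2RB	1
IL21	IL21R	1
IFNG	IFNGR1	1
IFNG	IFNGR2	1
TNF	TNFRSF1A	1
TNF	TNFRSF1B	1
LTA	TNFRSF1A	1
LTA	LTBR	1
LTB	LTBR	1
CD63	TIMP1	1
TIMP1	CD63	1
CD274	PDCD1	1
PDCD1LG2	PDCD1	1
CD80	CTLA4	1
CD86	CTLA4	1
CD80	CD28	1
CD86	CD28	1
ICOSLG	ICOS	1
TNFSF9	TNFRSF9	1
TNFSF4	TNFRSF4	1
TNFSF10	TNFRSF10A	1
TNFSF10	TNFRSF10B	1
FASLG	FAS	1
CD40LG	CD40	1
CD70	CD27	1
LGALS9	HAVCR2	1
HLA-E	KLRD1	1
HLA-E	KLRC1	1
B2M	KLRD1	1
B2M	LILRB1	1
B2M	LILRB2	1
VEGFA	FLT1	1
VEGFA	KDR	1
VEGFB	FLT1	1
VEGFC	FLT4	1
EGF	EGFR	1
TGFA	EGFR	1
AREG	EGFR	1
HGF	MET	1
FGF2	FGFR1	1
FGF2	FGFR2	1
PDGFA	PDGFRA	1
PDGFB	PDGFRB	1
IGF1	IGF1R	1
JAG1	NOTCH1	1
JAG2	NOTCH1	1
DLL1	NOTCH1	1
DLL4	NOTCH4	1
WNT5A	FZD5	1
WNT3A	FZD1	1
EFNB2	EPHB4	1
EFNA1	EPHA2	1
SEMA4D	PLXNB1	1
SEMA3A	NRP1	1
ICAM1	ITGAL	1
ICAM1	ITGB2	1
VCAM1	ITGA4	1
VCAM1	ITGB1	1
FN1	ITGB1	1
FN1	ITGA5	1
COL1A1	ITGB1	1
COL1A1	ITGA1	1
LAMB1	ITGB1	1
APP	CD74	1
MIF	CD74	1
MIF	CXCR4	1
CD47	SIRPA	1
THBS1	CD47	1
ANXA1	FPR1	1
GRN	SORT1	1
NAMPT	INSR	1
GAS6	AXL	1
PROS1	AXL	1
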