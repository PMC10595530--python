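pair_id	ligand_subunits	receptor_subunits	pathway	display
WNT5A_FZD2	WNT5A	FZD2	WNT	FZD2-WNT5A
TGFB1_TGFBR3	TGFB1	TGFBR3	TGFb	TGFB1-TGFBR3
TGFB1_TGFBR1_TGFBR2	TGFB1	TGFBR1+TGFBR2	TGFb	TGFB1-(TGFBR1+TGFBR2)
VEGFA_NRP1	VEGFA	NRP1	VEGF	NRP1-VEGFA
VEGFA_NRP2	VEGFA	NRP2	VEGF	NRP2-VEGFA
SPP1_CD44	SPP1	CD44	SPP1	SPP1-CD44
SEMA4D_PLXNB2	SEMA4D	PLXNB2	SEMA4	SEMA4D-PLXNB2
SEMA3A_NRP1	SEMA3A	NRP1	SEMA3	NRP1-SEMA3A
MDK_LRP1	MDK	LRP1	MK	LRP1-MDK
IGF1_IGF1R	IGF1	IGF1R	IGF	IGF1-IGF1R
ANXA1_FPR1	ANXA1	FPR1	ANNEXIN	FPR1-ANXA1
ANXA1_FPR2	ANXA1	FPR2	ANNEXIN	FPR2-ANXA1
ANXA1_FPR3	ANXA1	FPR3	ANNEXIN	FPR3-ANXA1
TNFSF10_TNFRSF10B	TNFSF10	TNFRSF10B	TRAIL	TNFSF10-TNFRSF10B
CD47_SIRPA	CD47	SIRPA	CD47	SIRPA-CD47
RPS19_C5AR1	RPS19	C5AR1	COMPLEMENT	C5AR1-RPS19
GAS6_AXL	GAS6	AXL	GAS	GAS6-AXL
NECTIN2_TIGIT	NECTIN2	TIGIT	NECTIN	NECTIN2-TIGIT
SELPLG_SELL	SELPLG	SELL	SELL	SELL-SELPLG
SPN_SIGLEC1	SPN	SIGLEC1	SIGLEC	SIGLEC1-SPN
LGALS9_HAVCR2	LGALS9	HAVCR2	GALECTIN	LGALS9-HAVCR2
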