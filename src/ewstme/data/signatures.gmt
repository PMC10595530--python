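hla_class_i	HLA class I antigen presentation genes	HLA-A	HLA-B	HLA-C	HLA-E	HLA-F	B2M
dysfunction	Inhibitory-receptor panel marking dysfunctional/exhausted T cells	LAG3	HAVCR2	TIGIT	PDCD1	CTLA4	BTLA	KLRG1	ENTPD1
antigen_presentation_costim	HLA class I/II plus T-cell costimulation genes	HLA-A	HLA-B	HLA-C	HLA-E	HLA-F	B2M	HLA-DRA	HLA-DRB1	HLA-DPA1	HLA-DPB1	HLA-DQA1	HLA-DQB1	CD40	CD70	CD80	CD83	CD86	TNFSF9	ICOSLG
costimulatory	Costimulatory genes scored as expressing fractions	CD70	CD80	CD83	CD86	TNFSF9
m1_polarization	Synthetic stand-in panel of classical (M1) macrophage activation genes	IL1B	TNF	IL6	IL12B	CXCL9	CXCL10	CXCL11	NOS2	FCGR1A	SOCS1	CD80	CD86
m2_polarization	Synthetic stand-in panel of alternative (M2) macrophage activation genes	CD163	MRC1	MSR1	STAB1	CCL22	IL10	TGFB1	APOE	GPNMB	LYVE1
pro_inflammatory	Synthetic stand-in pro-inflammatory cytokine/chemokine panel	IL1B	TNF	IL6	IL18	CCL3	CCL4	CXCL8	CCL5
anti_inflammatory	Synthetic stand-in anti-inflammatory/immunoregulatory panel	IL10	TGFB1	IL1RN	CD163	MRC1	CCL22	IL4R
dc_maturation	Synthetic stand-in dendritic-cell maturation panel (inflammatory-stimulus response genes)	CD83	CD86	CD80	CD40	CCR7	RELB	NFKB1	STAT3	IL12B	TRAF1
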