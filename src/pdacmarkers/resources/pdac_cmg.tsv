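cell_type	gene	provenance	parent
B cells	BLK	previously_used
B cells	BLNK	previously_used
B cells	CCR9	previously_used
B cells	CD19	previously_used
B cells	CD22	newly_selected
B cells	CD24	newly_selected
B cells	CR2	previously_used
B cells	HLA-DOB	previously_used
B cells	HLA-DQA1	previously_used
B cells	MEF2C	previously_used
B cells	MS4A1	previously_used
Plasma B cells	CD27	newly_selected	B cells
Plasma B cells	CD38	newly_selected	B cells
Plasma B cells	SLAMF7	newly_selected	B cells
Plasma B cells	TNFRSF17	newly_selected	B cells
Regulatory B cells	CD1D	newly_selected	B cells
Regulatory B cells	CD5	newly_selected	B cells
Regulatory B cells	IL10	newly_selected	B cells
Cytotoxic cells	GZMA	previously_used
Cytotoxic cells	GZMB	previously_used
Cytotoxic cells	GZMH	previously_used
Cytotoxic cells	KLRB1	previously_used
Cytotoxic cells	KLRD1	previously_used
Cytotoxic cells	KLRK1	previously_used
Cytotoxic cells	PRF1	previously_used
Cytotoxic cells	CTSW	previously_used
Cytotoxic cells	GNLY	previously_used
Dendritic cells	CCL13	previously_used
Dendritic cells	CD1A	newly_selected
Dendritic cells	CD1C	newly_selected
Dendritic cells	CD209	previously_used
Dendritic cells	HSD11B1	previously_used
Conventional Dendritic cells 1	BTLA	newly_selected	Dendritic cells
Conventional Dendritic cells 1	XCR1	newly_selected	Dendritic cells
Conventional Dendritic cells 1	DPP4	newly_selected	Dendritic cells
Conventional Dendritic cells 1	THBD	newly_selected	Dendritic cells
Conventional Dendritic cells 2	CD2	newly_selected	Dendritic cells
Conventional Dendritic cells 2	ITGAM	newly_selected	Dendritic cells
Conventional Dendritic cells 2	ITGAX	newly_selected	Dendritic cells
Plasmacytoid Dendritic cells	CLEC4C	newly_selected	Dendritic cells
Plasmacytoid Dendritic cells	IL3RA	newly_selected	Dendritic cells
Plasmacytoid Dendritic cells	NRP1	newly_selected	Dendritic cells
Macrophages	CD68	previously_used
Macrophages	FCGR2A	newly_selected
Antigen presenting cells	CCR7	newly_selected
Antigen presenting cells	CD80	newly_selected
Antigen presenting cells	CD86	newly_selected
M2 Macrophages	CD163	newly_selected	Macrophages
M2 Macrophages	CD36	newly_selected	Macrophages
M2 Macrophages	MRC1	newly_selected	Macrophages
Mast cells	C2	newly_selected
Mast cells	CMA1	previously_used
Mast cells	CTSG	previously_used
Mast cells	FCER1A	newly_selected
Mast cells	MS4A2	previously_used
Mast cells	PLAU	newly_selected
Mast cells	TPSAB1	previously_used
Monocytes	CD14	newly_selected
Monocytes	CD33	newly_selected
Monocytes	TLR2	newly_selected
Natural Killer cells	NCR1	previously_used
Natural Killer cells	XCL2	previously_used
Natural Killer CD56+ dim cells	IL21R	previously_used	Natural Killer cells
Natural Killer CD56+ dim cells	KIR3DL1	previously_used	Natural Killer cells
Neutrophils	CSF3R	previously_used
Neutrophils	FCGR3A	newly_selected
Neutrophils	S100A12	previously_used
T cells	CD3D	previously_used
T cells	CD3E	previously_used
T cells	CD3G	previously_used
T cells	CD6	previously_used
T cells	SH2D1A	previously_used
CD4+ T cells	CD4	newly_selected	T cells
CD4+ T cells	SELL	newly_selected	T cells
CD8+ T cells	CD8A	previously_used	T cells
CD8+ T cells	CD8B	previously_used	T cells
Exhausted CD8+ T cells	CD244	previously_used	CD8+ T cells
Exhausted CD8+ T cells	HAVCR2	newly_selected	CD8+ T cells
Exhausted CD8+ T cells	LAG3	previously_used	CD8+ T cells
Exhausted CD8+ T cells	PDCD1	newly_selected	CD8+ T cells
Exhausted CD8+ T cells	TIGIT	newly_selected	CD8+ T cells
Helper 1 T cells	TBX21	previously_used	T cells
Helper 1 T cells	ALCAM	newly_selected	T cells
Helper 1 T cells	CD70	previously_used	T cells
Regulatory T cells	FOXP3	previously_used	T cells
Regulatory T cells	CD274	newly_selected	T cells
Regulatory T cells	IDO1	newly_selected	T cells
Regulatory T cells	IL2RA	newly_selected	T cells
Regulatory T cells	TNFRSF18	newly_selected	T cells
CD45+	PTPRC	previously_used
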