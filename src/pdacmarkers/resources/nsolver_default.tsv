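cell_type	gene	provenance	parent
B cells	BLK	on_panel
B cells	CD19	on_panel
B cells	MS4A1	on_panel
B cells	TNFRSF17	on_panel
B cells	FCRL2	off_panel
B cells	KIAA0125	off_panel
B cells	PNOC	off_panel
B cells	SPIB	off_panel
B cells	TCL1A	off_panel
Cytotoxic cells	GZMA	on_panel
Cytotoxic cells	GZMB	on_panel
Cytotoxic cells	GZMH	on_panel
Cytotoxic cells	KLRB1	on_panel
Cytotoxic cells	KLRD1	on_panel
Cytotoxic cells	KLRK1	on_panel
Cytotoxic cells	PRF1	on_panel
Cytotoxic cells	CTSW	on_panel
Cytotoxic cells	GNLY	on_panel
Cytotoxic cells	NKG7	off_panel
Dendritic cells	CCL13	on_panel
Dendritic cells	CD209	on_panel
Dendritic cells	HSD11B1	on_panel
Macrophages	CD163	on_panel
Macrophages	CD68	on_panel
Macrophages	CD84	on_panel
Macrophages	MS4A4A	off_panel
Mast cells	MS4A2	on_panel
Mast cells	TPSAB1	on_panel
Mast cells	CPA3	off_panel
Mast cells	HDC	off_panel
Mast cells	TPSB2	off_panel
Natural Killer cells	NCR1	on_panel
Natural Killer cells	XCL1	off_panel
Natural Killer cells	XCL2	on_panel
Natural Killer CD56+ dim cells	IL21R	on_panel	Natural Killer cells
Natural Killer CD56+ dim cells	KIR3DL1	on_panel	Natural Killer cells
Natural Killer CD56+ dim cells	KIR2DL3	on_panel	Natural Killer cells
Natural Killer CD56+ dim cells	KIR3DL2	on_panel	Natural Killer cells
Neutrophils	CEACAM3	off_panel
Neutrophils	CSF3R	on_panel
Neutrophils	FCAR	off_panel
Neutrophils	FCGR3B	off_panel
Neutrophils	FPR1	off_panel
Neutrophils	S100A12	on_panel
Neutrophils	SIGLEC5	off_panel
T cells	CD3D	on_panel
T cells	CD3E	on_panel
T cells	CD3G	on_panel
T cells	CD6	on_panel
T cells	SH2D1A	on_panel
T cells	TRAT1	off_panel
CD8+ T cells	CD8A	on_panel	T cells
CD8+ T cells	CD8B	on_panel	T cells
Exhausted CD8+ T cells	CD244	on_panel	CD8+ T cells
Exhausted CD8+ T cells	EOMES	on_panel	CD8+ T cells
Exhausted CD8+ T cells	LAG3	on_panel	CD8+ T cells
Exhausted CD8+ T cells	PTGER4	on_panel	CD8+ T cells
Helper 1 T cells	TBX21	on_panel	T cells
Regulatory T cells	FOXP3	on_panel	T cells
CD45+	PTPRC	on_panel
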