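cell_type	gene	provenance	parent
B cells	BLK	shared_with_default
B cells	CD19	shared_with_default
B cells	CD22	newly_defined
B cells	CR2	newly_defined
B cells	MS4A1	shared_with_default
Plasma B cells	CD27	newly_defined	B cells
Plasma B cells	CD38	newly_defined	B cells
Plasma B cells	SLAMF7	newly_defined	B cells
Plasma B cells	TNFRSF17	newly_defined	B cells
Regulatory B cells	CD1D	newly_defined	B cells
Regulatory B cells	CD5	newly_defined	B cells
Cytotoxic cells	GZMA	shared_with_default
Cytotoxic cells	GZMB	shared_with_default
Cytotoxic cells	GZMH	shared_with_default
Cytotoxic cells	KLRB1	shared_with_default
Cytotoxic cells	KLRD1	shared_with_default
Cytotoxic cells	KLRK1	shared_with_default
Cytotoxic cells	PRF1	shared_with_default
Dendritic cells	CD1A	newly_defined
Dendritic cells	CD1C	newly_defined
Conventional Dendritic cells 1	BTLA	newly_defined	Dendritic cells
Conventional Dendritic cells 1	XCR1	newly_defined	Dendritic cells
Conventional Dendritic cells 2	ITGAM	newly_defined	Dendritic cells
Conventional Dendritic cells 2	ITGAX	newly_defined	Dendritic cells
Macrophages	CD68	shared_with_default
Macrophages	FCGR2A	newly_defined
Antigen presenting cells	CD80	newly_defined
Antigen presenting cells	CD86	newly_defined
M2 Macrophages	CD163	newly_defined	Macrophages
M2 Macrophages	MRC1	newly_defined	Macrophages
Mast cells	MS4A2	shared_with_default
Mast cells	TPSAB1	shared_with_default
Monocytes	CD14	newly_defined
Monocytes	CD33	newly_defined
Monocytes	TLR2	newly_defined
Natural Killer cells	NCR1	shared_with_default
Natural Killer CD56+ dim cells	KIR3DL1	shared_with_default	Natural Killer cells
Neutrophils	CSF3R	shared_with_default
Neutrophils	FCGR3A	newly_defined
T cells	CD3D	shared_with_default
T cells	CD3E	shared_with_default
T cells	CD3G	shared_with_default
T cells	CD6	shared_with_default
T cells	SH2D1A	shared_with_default
CD4+ T cells	CD4	newly_defined	T cells
CD4+ T cells	SELL	newly_defined	T cells
CD8+ T cells	CD8A	shared_with_default	T cells
CD8+ T cells	CD8B	shared_with_default	T cells
Exhausted CD8+ T cells	LAG3	shared_with_default	CD8+ T cells
Exhausted CD8+ T cells	PDCD1	newly_defined	CD8+ T cells
Exhausted CD8+ T cells	TIGIT	newly_defined	CD8+ T cells
Helper 1 T cells	TBX21	shared_with_default	T cells
Regulatory T cells	FOXP3	shared_with_default	T cells
Regulatory T cells	IL2RA	newly_defined	T cells
CD45+	PTPRC	shared_with_default
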