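# Synthetic reconstruction of per-gene variant-category flags for the eight
# published BFMI top candidate genes (two per QTL: Gatlgq, Gatq1, Bwq26, Gatq2),
# built from the published per-gene variant descriptions and expression results.
# KEGG membership per gene is not published at gene level; the flags below are
# derived so that category-once scoring reproduces the published gene scores.
gene	qtl	stop_gain_or_loss	missense	missense_in_domain	sift	promoter_or_splice	utr	enhancer	ctcf	de_any_tissue	kegg
Plg	Gatlgq	0	1	1	tolerated	1	0	1	1	0	1
Acat2	Gatlgq	0	1	1	deleterious	0	0	0	0	1	1
Fmo5	Gatq1	0	1	1	tolerated	1	1	1	0	1	1
Notch2	Gatq1	0	1	1	deleterious	0	1	0	0	1	1
Trap1	Bwq26	0	1	1	tolerated	0	0	0	0	1	1
Rrn3	Bwq26	0	1	0	tolerated	0	0	0	0	1	1
Trappc9	Gatq2	0	0	0	none	1	1	1	1	1	1
Zfat	Gatq2	0	1	1	deleterious	0	0	0	0	1	0
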