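# Non-synonymous variants in 8 inbred rat lines (transcription of a published table).
# The Casp12 exon-7 1 bp insertion is present in every strain and restores the reading
# frame relative to the reference assembly; it is encoded as variant '1bp_ins' with
# class 'unlikely'. One ambiguous mark in the printed ACI_N row was dropped.
strain	gene	variant	shading_class
ACI_N	Casp1	Q343R	unlikely
ACI_N	Casp12	1bp_ins	unlikely
BN_SsN	Casp12	1bp_ins	unlikely
BUF_N	Casp1	Q343R	unlikely
BUF_N	Casp11	V60A	unlikely
BUF_N	Casp12	1bp_ins	unlikely
F344_N	Casp1	Q343R	unlikely
F344_N	Casp11	V60A	unlikely
F344_N	Casp12	1bp_ins	unlikely
M520_N	Casp1	Q343R	unlikely
M520_N	Casp11	V60A	unlikely
M520_N	Casp12	1bp_ins	unlikely
MR_N	Casp1	Q343R	unlikely
MR_N	Casp11	F115L	potential
MR_N	Casp12	1bp_ins	unlikely
WKY_N	Casp1	Q343R	unlikely
WKY_N	Casp11	F115L	potential
WKY_N	Casp12	1bp_ins	unlikely
WN_N	Casp1	Q343R	unlikely
WN_N	Casp12	1bp_ins	unlikely
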