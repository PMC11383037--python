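# Non-synonymous variants in 16 inbred mouse lines (transcription of a published table).
# Column-to-gene grouping chosen to be consistent with the published avoid/clean strain
# lists (the printed layout is typographically ambiguous for a few columns); shading is
# encoded cell-wise: 'unlikely' (residue shared with another rodent), 'potential'
# (alters a highly conserved site). Strains with no variants carry a single 'none' row.
strain	gene	variant	shading_class
129S1_SvImJ	Casp11	5bp_del	potential
129S1_SvImJ	Casp11	C331Y	potential
129S1_SvImJ	Casp12	E46D	potential
129S1_SvImJ	Casp12	M130I	potential
129S1_SvImJ	Casp12	L137I	potential
cAST_EiJ	Casp1	R33K	unlikely
cAST_EiJ	Casp11	G257E	potential
cAST_EiJ	Casp12	M130I	potential
cAST_EiJ	Casp12	L137I	unlikely
cAST_EiJ	Casp12	F154L	potential
cAST_EiJ	Casp12	N311S	unlikely
cAST_EiJ	Casp12	N330T	potential
pWK_PhJ	Casp1	R33K	unlikely
pWK_PhJ	Casp11	C331Y	potential
pWK_PhJ	Casp12	L137I	unlikely
pWK_PhJ	Casp12	Q153K	potential
pWK_PhJ	Casp12	E217K	potential
pWK_PhJ	Casp12	N311S	unlikely
sPRET_EiJ	Casp1	R33K	unlikely
sPRET_EiJ	Casp11	E163Q	unlikely
sPRET_EiJ	Casp12	A3V	unlikely
sPRET_EiJ	Casp12	D24N	unlikely
sPRET_EiJ	Casp12	L137I	unlikely
sPRET_EiJ	Casp12	Q230H	unlikely
sPRET_EiJ	Casp12	H270R	unlikely
sPRET_EiJ	Casp12	N311S	unlikely
wSB_EiJ	Casp12	I15L	potential
wSB_EiJ	Casp12	E46D	potential
wSB_EiJ	Casp12	P105L	potential
aKR_J	Casp12	I15L	potential
aKR_J	Casp12	E46D	potential
aKR_J	Casp12	P105L	potential
cBA_J	Casp11	N152K	potential
cBA_J	Casp12	E46D	potential
nOD_ShiLtJ	Casp11	H305C	potential
IP_J	Casp11	E126K	potential
bALB_cJ	none	none	none
c57BL_6NJ	none	none	none
a_J	none	none	none
nZO_HILtJ	none	none	none
fVB_NJ	none	none	none
dBA_2J	none	none	none
c3H_HeJ	none	none	none
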