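position	location	peptide_contacts	reference_residue	observed_residues
9	floor	P2	F	YTSFH
114	sidewall	P5,P6,P7	H	QHPEDTRSN
116	floor	P9	Y	YHTFSDNV
152	mouth	P7	V	EVRWMA
156	mouth	P3	L	WLQSRAG
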