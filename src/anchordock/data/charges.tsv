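# Partial charges (e), united-hydrogen heavy-atom model.
# residue '*' = backbone defaults applied to every residue; atoms not
# listed carry zero charge.  Net charge: ASP/GLU -1, LYS/ARG +1, else 0.
residue	atom	charge
*	N	-0.10
*	CA	0.05
*	C	0.55
*	O	-0.50
SER	CB	0.38
SER	OG	-0.38
THR	CB	0.38
THR	OG1	-0.38
CYS	CB	0.20
CYS	SG	-0.20
TYR	CZ	0.40
TYR	OH	-0.40
TRP	CD1	0.10
TRP	NE1	-0.10
ASN	CG	0.55
ASN	OD1	-0.50
ASN	ND2	-0.05
GLN	CD	0.55
GLN	OE1	-0.50
GLN	NE2	-0.05
HIS	ND1	-0.20
HIS	NE2	-0.20
HIS	CE1	0.40
MET	CG	0.05
MET	SD	-0.10
MET	CE	0.05
ASP	CG	0.40
ASP	OD1	-0.70
ASP	OD2	-0.70
GLU	CD	0.40
GLU	OE1	-0.70
GLU	OE2	-0.70
LYS	CE	0.40
LYS	NZ	0.60
ARG	NE	-0.10
ARG	CZ	0.60
ARG	NH1	0.25
ARG	NH2	0.25
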