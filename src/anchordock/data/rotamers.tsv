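# Backbone-independent rotamer library: modal chi sets with priors.
# Priors sum to 1 per residue; unused chi columns left empty.
residue	prior	chi1	chi2	chi3	chi4
ALA	1.0
GLY	1.0
SER	0.48	-65
SER	0.30	180
SER	0.22	65
CYS	0.50	-65
CYS	0.30	180
CYS	0.20	65
THR	0.45	-60
THR	0.40	60
THR	0.15	180
VAL	0.55	175
VAL	0.30	-60
VAL	0.15	65
LEU	0.60	-65	175
LEU	0.30	-175	65
LEU	0.10	-85	65
ILE	0.60	-65	170
ILE	0.15	180	165
ILE	0.15	-60	-60
ILE	0.10	62	170
PRO	0.55	-27	36
PRO	0.45	28	-35
MET	0.30	-65	180	75
MET	0.30	-65	180	-75
MET	0.20	-65	180	180
MET	0.20	180	180	75
PHE	0.50	-65	90
PHE	0.35	180	80
PHE	0.15	62	90
TYR	0.50	-65	90
TYR	0.35	180	80
TYR	0.15	62	90
TRP	0.35	-65	95
TRP	0.25	180	-105
TRP	0.20	-65	-5
TRP	0.20	62	-90
ASP	0.50	-70	-15
ASP	0.35	180	15
ASP	0.15	62	5
ASN	0.45	-65	-20
ASN	0.35	180	30
ASN	0.20	62	25
GLU	0.40	-65	180	-10
GLU	0.35	180	180	5
GLU	0.25	-60	-60	-30
GLN	0.40	-65	180	-20
GLN	0.35	180	180	20
GLN	0.25	-60	-60	-40
LYS	0.40	-65	180	180	180
LYS	0.35	180	180	180	180
LYS	0.25	-60	-60	180	180
ARG	0.35	-65	180	180	180
ARG	0.30	180	180	180	180
ARG	0.20	-65	180	-65	180
ARG	0.15	-60	-60	180	180
HIS	0.40	-65	-70
HIS	0.30	180	60
HIS	0.30	62	-75
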