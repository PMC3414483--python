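# United-hydrogen heavy-atom nonbonded parameters, keyed by element.
# eps in kcal/mol, rmin_half and gb_radius in Angstrom.
element	eps	rmin_half	gb_radius	gb_screen
C	0.086	1.908	1.70	0.72
N	0.170	1.824	1.55	0.79
O	0.210	1.661	1.50	0.85
S	0.250	2.000	1.80	0.96
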