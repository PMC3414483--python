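pdb_id	resolution	sequence
1AKJ	2.65	ILKEPVHGV
1AO7	2.6	LLFGYPVYV
1B0G	2.5	ALWGFFPVL
1EEY	2.25	ILSALVGIV
1EEZ	2.3	ILSALVGIL
1HHG	2.6	TLTSCNTSV
1HHI	2.5	GILGFVFTL
1I1F	2.8	FLKEPVHGV
1I1Y	2.2	YLKEPVHGV
1I7R	2.2	FAPGFFPYL
1I7T	2.8	ALWGVFPVL
1I7U	1.8	ALWGFVPVL
1JHT	2.15	ALGIGILTV
1QEW	2.2	FLWGPRALV
1QR1	2.4	IISAVVGIL
1QRN	2.8	LLFGYAVYV
1QSE	2.8	LLFGYPRYV
1QSF	2.8	LLFGYPVAV
1S8D	2.2	SLANTVATL
1S9W	2.2	SLLMWITQC
1S9X	2.5	SLLMWITQA
1S9Y	2.3	SLLMWITQS
1T1W	2.2	SLFNTIAVL
1T1X	2.2	SLYLTVATL
1T1Y	2	SLYNVVATL
1T1Z	1.9	ALYNTAAAL
1T20	2.2	SLYNTIATL
1T21	2.19	SLYNTVATL
1TVB	1.8	ITDQVPFSV
1TVH	1.8	IMDQVPFSV
2BNQ	1.7	SLLMWITQV
2GIT	1.7	LLFGKPVYV
2GTW	1.55	LAGIGILTV
2GUO	1.9	AAGIGILTV
2V2X	1.6	SLFNTVATL
2X4O	2.3	KLTPLCVTL
2X4R	2.3	NLVPMVATV
2X4S	2.55	AMDSNTLEL
3D25	1.3	VLHDDLLEA
3FQT	1.8	GLLGSPVRA
3FQW	1.93	RVASPTSGV
3FT4	1.9	VLRDDLLEA
3GSQ	2.12	NLVPSVATV
3GSR	1.95	NLVPVVATV
3GSU	1.8	NLVPTVATV
3GSV	1.9	NLVPQVATV
3GSW	1.81	NLVPMVAAV
3GSX	2.1	NLVPMVAVV
3H7B	1.88	MLWGYLQYV
3KLA	1.65	SLLMWITQL
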