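# Bonded parameters for beta(1->2)-linked glucopyranose chains.
# Bead numbering refers to the first linked pair of residues; +4n for later linkages.
kind	beads	k	ref	mult	form	flags
bond	B1-B4	10000	0.265	.	harmonic	.
bond	B2-B3	50000	0.263	.	harmonic	.
bond	B3-B4	24000	0.272	.	harmonic	.
bond	B2-B4	50000	0.290	.	harmonic	.
bond	B2-B7	6000	0.274	.	harmonic	.
bond	B4-B7	600	0.530	.	harmonic	.
angle	B1-B4-B2	200	80	.	g96	.
angle	B1-B4-B3	400	132	.	g96	.
angle	B3-B2-B7	30	88	.	g96	.
angle	B1-B2-B7	60	165	.	restricted	.
angle	B2-B7-B6	50	97	.	g96	.
angle	B2-B7-B8	40	148	.	restricted	.
improper	B4-B3-B2-B1	150	11	.	improper	.
improper	B7-B6-B8-B2	300	15	.	improper	.
improper	B2-B4-B3-B7	200	1	.	improper	.
dihedral	B3-B2-B7-B6	-22	-141	1	proper	.
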