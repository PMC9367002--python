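# Bonded parameters for beta(1->3)-linked glucopyranose chains.
# Bead numbering refers to the first linked pair of residues; +4n for later linkages.
kind	beads	k	ref	mult	form	flags
bond	B1-B4	10000	0.268	.	harmonic	.
bond	B2-B3	38000	0.240	.	harmonic	.
bond	B3-B4	24000	0.287	.	harmonic	.
bond	B2-B4	50000	0.287	.	harmonic	.
bond	B2-B7	12000	0.250	.	harmonic	.
angle	B1-B4-B2	220	78	.	g96	.
angle	B1-B4-B3	400	123	.	g96	.
angle	B3-B2-B7	60	75	.	g96	.
angle	B1-B2-B7	80	148	.	restricted	.
angle	B2-B7-B6	110	128	.	g96	.
angle	B2-B7-B8	40	65	.	g96	.
improper	B4-B3-B2-B1	120	15	.	improper	.
improper	B7-B2-B8-B6	200	22	.	improper	.
improper	B2-B7-B3-B4	200	3	.	improper	.
dihedral	B3-B2-B7-B6	-20	-174	1	proper	.
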