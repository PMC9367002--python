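# Bonded parameters for alpha(1->6)-linked glucopyranose chains.
# Bead numbering refers to the first linked pair of residues; +4n for later linkages.
# The B1-B9 bond spans two linkages and is emitted only where residue n+3 exists.
kind	beads	k	ref	mult	form	flags
bond	B1-B4	21000	0.251	.	harmonic	.
bond	B2-B3	35000	0.280	.	harmonic	.
bond	B2-B4	60000	0.322	.	harmonic	.
bond	B3-B4	24000	0.289	.	harmonic	.
bond	B2-B5	13000	0.225	.	harmonic	.
bond	B3-B7	2400	0.820	.	harmonic	.
bond	B1-B9	180	0.790	.	harmonic	.
angle	B1-B4-B2	600	80	.	g96	.
angle	B1-B4-B3	560	135	.	g96	.
angle	B3-B2-B5	180	109	.	g96	.
angle	B4-B2-B5	100	105	.	g96	.
angle	B2-B5-B6	28	122	.	restricted	.
improper	B4-B2-B3-B1	250	-7	.	improper	.
improper	B2-B3-B5-B4	110	-74	.	improper	.
dihedral	B3-B2-B5-B6	-3	155	2	proper	.
dihedral	B2-B5-B6-B7	-3	170	5	proper	.
dihedral	B2-B5-B6-B7	3	60	1	proper	.
dihedral	B2-B4-B8-B6	5	-25	1	proper	.
dihedral	B2-B4-B8-B6	-4	165	3	proper	.
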