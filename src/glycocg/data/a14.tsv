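# Bonded parameters for alpha(1->4)-linked glucopyranose chains.
# Bead numbering refers to the first linked pair of residues (B1-B4 reducing-end
# residue, B5-B8 next residue); terms for the n-th linkage follow by adding 4n.
# flags: nonreducing_end = emit the term only at the nonreducing terminus.
kind	beads	k	ref	mult	form	flags
bond	B1-B4	18000	0.251	.	harmonic	.
bond	B2-B3	32000	0.280	.	harmonic	.
bond	B3-B4	34000	0.279	.	harmonic	.
bond	B2-B4	60000	0.292	.	harmonic	.
bond	B2-B8	32000	0.280	.	harmonic	.
angle	B1-B4-B2	340	86	.	g96	.
angle	B1-B4-B3	580	142	.	g96	.
angle	B3-B2-B8	310	103	.	g96	.
angle	B4-B2-B8	180	103	.	restricted	.
angle	B1-B2-B8	210	105	.	g96	.
angle	B2-B8-B5	30	107	.	g96	.
angle	B2-B8-B6	240	148	.	restricted	.
angle	B2-B8-B7	120	99	.	g96	.
improper	B4-B3-B2-B1	200	9	.	improper	nonreducing_end
improper	B8-B2-B7-B6	170	22.3	.	improper	.
improper	B2-B8-B4-B3	300	-67	.	improper	.
dihedral	B4-B2-B8-B6	-12.8	161	1	proper	.
dihedral	B3-B2-B8-B7	-2.2	165	1	proper	.
dihedral	B1-B3-B7-B5	-3.6	-72	5	proper	.
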