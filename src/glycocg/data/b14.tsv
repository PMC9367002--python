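# Bonded parameters for beta(1->4)-linked glucopyranose chains.
# Bead numbering refers to the first linked pair of residues; +4n for later linkages.
kind	beads	k	ref	mult	form	flags
bond	B1-B4	14100	0.250	.	harmonic	.
bond	B2-B3	37500	0.268	.	harmonic	.
bond	B3-B4	27000	0.273	.	harmonic	.
bond	B2-B4	53200	0.257	.	harmonic	.
bond	B2-B8	7500	0.267	.	harmonic	.
bond	B2-B6	16300	0.520	.	harmonic	.
bond	B4-B8	3770	0.542	.	harmonic	.
angle	B1-B4-B2	220	91	.	g96	.
angle	B1-B4-B3	159	143	.	restricted	.
angle	B3-B2-B8	245	115	.	g96	.
angle	B1-B2-B8	350	127	.	g96	.
angle	B2-B8-B5	16	123	.	g96	.
angle	B2-B8-B7	52	93	.	g96	.
improper	B4-B3-B2-B1	200	9	.	improper	nonreducing_end
improper	B8-B2-B7-B6	212	11	.	improper	.
improper	B2-B3-B8-B4	229	9	.	improper	.
dihedral	B3-B2-B8-B7	-35	-135	1	proper	.
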