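# Bonded parameters for free alpha-/beta-glucopyranose monomers.
# Bond: harmonic V = 1/2 k (b-b0)^2 (GROMACS bonds type 1); angle forms: g96 (type 2)
# or restricted (type 10); improper: harmonic in the wrapped angle (dihedrals type 2).
# k units as published: bonds kJ/mol/nm^4 header (interpreted harmonic, see docs),
# angles kJ/mol, impropers kJ/mol/deg^2; reference values nm or deg.
kind	beads	alpha_k	alpha_ref	beta_k	beta_ref	mult	form	flags
bond	B1-B4	12000	0.268	12000	0.268	.	harmonic	.
bond	B2-B3	20000	0.284	24000	0.291	.	harmonic	.
bond	B3-B4	28000	0.291	28000	0.291	.	harmonic	.
bond	B2-B4	28000	0.342	32000	0.355	.	harmonic	.
angle	B1-B4-B2	340	85	450	81	.	g96	.
angle	B1-B4-B3	580	132	580	132	.	g96	.
improper	B4-B3-B2-B1	200	9	200	9	.	improper	.
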