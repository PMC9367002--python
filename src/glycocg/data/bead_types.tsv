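# Per-residue bead definitions. Odd beads carry the polar outward regions
# (hydroxymethyl / diol), even beads the less polar ring backbone.
# s_ring_type is the alternative assignment with the regular ring bead shrunk to S.
index	name	default_type	s_ring_type	mapped_region
1	B1	TP3	TP3	hydroxymethyl
2	B2	SN4	SN4	ring-O+anomeric-C
3	B3	P3	SP3	diol-or-hydroxyethyl
4	B4	TN4	TN4	hydroxyethyl
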