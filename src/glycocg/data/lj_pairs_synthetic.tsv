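# SYNTHETIC Lennard-Jones pair table for the bead types used by the carbohydrate
# model. These are NOT calibrated interaction parameters: they are constructed from
# size-class sigmas (R 0.47, S 0.41, T 0.34 nm; arithmetic mean per pair) and
# per-chemical-class well depths (P3 4.5, N4 3.4 kJ/mol; geometric mean per pair),
# with C6 = 4*eps*sigma^6 and C12 = 4*eps*sigma^12. Intended for testing the
# nonbonded machinery; replace with a calibrated table for production use.
type_a	type_b	C6	C12
TP3	TP3	2.780648e-02	4.295557e-05
TP3	SN4	4.351042e-02	1.209988e-04
TP3	P3	7.943331e-02	3.505361e-04
TP3	TN4	2.417014e-02	3.733814e-05
TP3	SP3	5.005646e-02	1.392027e-04
SN4	SN4	6.460142e-02	3.068635e-04
SN4	P3	1.135329e-01	8.238304e-04
SN4	TN4	3.782043e-02	1.051754e-04
SN4	SP3	7.432054e-02	3.530303e-04
P3	P3	1.940259e-01	2.091447e-03
P3	TN4	6.904557e-02	3.046955e-04
P3	SP3	1.306136e-01	9.477736e-04
TN4	TN4	2.100934e-02	3.245532e-05
TN4	SP3	4.351042e-02	1.209988e-04
SP3	SP3	8.550188e-02	4.061428e-04
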