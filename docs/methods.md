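# Methods

## Scope and model

`glycocg` implements a four-bead-per-residue coarse-grained description of
glucopyranose-based saccharides in the Martini 3 style: monomers (α or β
anomer) and homopolymer chains joined by β(1→2), β(1→3), α(1→4), β(1→4) or
α(1→6) glycosidic linkages.  The ⁴C₁ chair of glucopyranose is assumed rigid;
ring puckering and chair inversion are outside the model, as are
functionalized sugars, non-glucose hexopyranoses and branched heteropolymers.
Mixed-linkage chains are accepted syntactically but warn loudly: the
parameter set was validated on homopolymers only.

## Parameter registry

Bonded parameters live in TSV files, one per parameter table (monomer plus
one per linkage type), loaded through `ForceFieldTables`.  Storing them as
data rather than code lets alternative, chemically sound bead assignments be
swapped in by configuration; the shipped default is the P3 + N4 combination
(B1=TP3, B2=SN4, B3=P3, B4=TN4), with an `s_ring` variant that replaces the
regular ring bead by SP3.

Chain expansion follows the "+4n" rule: linkage-table rows are written in
first-linkage numbering (beads 1–8, or 1–9 for α(1→6)); the n-th linkage
repeats them with every bead index raised by 4n.  Rows whose beads all lie
within one residue (indices ≤ 4) are intra-ring terms and are stamped once
per residue — they *replace* the free-monomer parameters, which apply only to
n = 1, because each linkage table is self-contained.  Rows reaching past bead
4 are glycosidic terms stamped once per linkage; a replica whose shifted
indices would exceed the chain (only the α(1→6) B1–B9 bond, which spans two
linkages) is dropped at the chain end.  The ring improper of the two (1→4)
tables is flagged for the nonreducing end only and is emitted solely at
residue n (residue 1 is the reducing end by convention); the other linkage
tables carry no such flag, so their ring improper is emitted for every
residue, exactly as tabulated.

Two deliberate conventions:

- **Bond units.** The stretch constants are tabulated with a nm⁻⁴
  superscript, which would suit a quartic (G96-type) bond, but the functional
  form is bound to the harmonic GROMACS "bonds, type 1".  The registry keeps
  the numbers exactly as printed and evaluates them harmonically,
  V = ½ k_b (b − b₀)²; the superscript is treated as a typographical slip.
  Users exporting to MD engines should be aware of this binding.
- **Masses.** Bead masses are not part of the published parameter set; the
  Martini 3 convention (R = 72, S = 54, T = 36 Da) is used and can be
  overridden in the configuration.  Masses only matter for file output and
  mass-weighted descriptors — the Monte Carlo sampler is mass-free.

Lennard-Jones C6/C12 values for the bead types are likewise not part of the
bonded tables; they are read from a user-supplied pair table.  The shipped
`lj_pairs_synthetic.tsv` is a synthetic stand-in built from size-class sigmas
(R 0.47, S 0.41, T 0.34 nm, arithmetic combination) and per-chemical-class
well depths (P3 4.5, N4 3.4 kJ/mol, geometric combination).  It exercises
the nonbonded code paths with realistic magnitudes but is **not calibrated**;
aggregation or partitioning behaviour computed with it is not meaningful.

## Energetics

Angles are degrees at every interface and radians internally.  The improper
deviation ξ − ξ₀ is wrapped minimum-image to (−180°, 180°], so k_ξ (given per
squared degree) always multiplies the short way around.  The restricted bend
divides the cosine-harmonic form by sin²θ and is reported as +∞ within 10⁻⁶
degrees of 0°/180° rather than NaN; inside the structure relaxer the
denominator is instead clamped (sin²θ ≥ 10⁻⁶) so gradients stay finite and
push the triplet away from collinearity.  The LJ sum runs over all
non-excluded pairs within the cutoff (default 1.1 nm), with the potential
shifted by its cutoff value so it vanishes exactly there; the unshifted form
is available via `shift=False`.  Exclusions are exactly the first covalent
neighbours (the bonded pairs), per the force field's build-up assumption.

Analytic gradients of all bonded terms back the structure relaxer; their
correctness is pinned by the test suite against the scalar energy functions
and a brute-force double-loop oracle.

## Initial structures

No construction algorithm is prescribed by the force field, so the generator
is the package's own: a relaxed four-bead residue template is grown residue
by residue along the chain axis, relaxing the partial chain after each
addition — first on bonds and angles only (whose minima are mutually
compatible), then with torsions switched on — and finishing with a full
relaxation by L-BFGS.  A small seeded jitter (σ = 0.01 nm) makes the result
deterministic per seed while breaking symmetry.  The product is checked
against explicit tolerances: every bond within 10% of b₀, every angle within
25° of θ₀, no bead pair closer than 0.15 nm, finite energy; failing attempts
are retried with derived seeds and a `RuntimeError` is raised after eight.

One force-field feature needs care here: the α(1→6) B1–B9 bond is very soft
(k_b = 180) and spans two linkages, and at the frustrated bonded minimum it
sits ~13% above b₀ (an energy cost well under 2 kJ/mol).  The final
relaxation therefore adds a steep penalty outside ±8% of b₀ for bonds that
would otherwise drift out of the advertised tolerance; this biases the
*starting structure* only, never the sampling or the reported energies.

## Atomistic mapping and fixtures

Mapping is centre-of-geometry: each bead is the unweighted mean of its atom
group, aliphatic hydrogens included and hydroxyl hydrogens excluded.  The
published mapping names molecular regions rather than atom lists, so the
concrete assignment is a documented reconstruction: B1 ← {C6, O6, H61, H62};
B2 ← {O5, C1, H1} plus the anomeric O1 at the reducing end; B3 ← {C2, O2,
C3, O3, H2, H3}; B4 ← {C4, O4, C5, H4, H5}.  A glycosidic oxygen belongs to
the bead of its parent carbon (O4 → B4, O6 → B1, O2/O3 → B3), which keeps
the groups identical in every linkage context.  Note the heavy-atom counts
(2/2–3/4/3) track but do not exactly equal the nominal T/S/R atom counts of
the bead sizes; the published size assignment is chemical, not purely
arithmetic.

The fixture generator emits idealized chair-like glucopyranose residues with
CHARMM-style atom names and is labelled synthetic: it stands in for
force-field-minimized atomistic structures in mapping tests and makes no
claim of chemical accuracy beyond correct atom bookkeeping (reducing-end O1,
one glycosidic oxygen per linkage, hydroxyl hydrogens consumed by linkages).

## Sampling

The sampler is Metropolis Monte Carlo over single-bead displacements
(uniform in a cube of half-width `step_size`), not MD: the validation
quantities are ensemble geometric distributions, which MC reproduces without
force evaluation.  The proposal is symmetric, so detailed balance holds by
construction; temperature enters only through k_B·T (k_B = 0.0083145
kJ mol⁻¹ K⁻¹).  The full energy is recomputed per trial move — systems here
are tens of beads, so vectorized full recomputation is fast and avoids
incremental-update bookkeeping.  Moves into +∞ (restricted-bend
collinearity) are rejected naturally.  A burn-in of min(n_steps/5, 5000)
steps precedes frame collection.

Default step sizes in tests and the acceptance script were chosen for
acceptance rates in the 0.05–0.6 range on the systems sampled; stiff
restricted-bend linkages (β(1→2), β(1→3), α(1→6)) accept least, mirroring
their need for shorter MD timesteps.

Descriptor summaries (mean ± SD) use streaming Welford accumulation, checked
against two-pass numpy statistics to 10⁻¹² relative.  Default selections
follow the convention of analysing the central residue(s) of a chain.  The
torsion histogram covers (−180°, 180°] with a bin width that must divide
360°; the float-division residual is absorbed into the modal bin so the
probabilities sum to exactly one.  SASA is Shrake–Rupley with a deterministic
Fibonacci sphere (default 1000 points, probe 0.14 nm); bead radii default to
half the size-class sigma (R 0.235, S 0.205, T 0.17 nm) since the force
field publishes no radii.

## Validation strategy and problem sizes

Desk-scale validation rests on (i) bit-exact fidelity of generated
topologies to the published tables, (ii) structural bookkeeping (4 beads per
residue, affine term counts in chain length for n ∈ {1, 2, 3, 8}, exclusions
equal to bonded pairs), (iii) analytic properties of every energy term
(minima located by independent numerical minimization; rigid-motion
invariance to 10⁻⁹ relative; equality with an O(n²) double-loop oracle on a
32-bead chain; an LJ potential exactly zero at the cutoff), (iv) low-T MC
parameter recovery on minimal systems — reference geometry within 1%,
harmonic bond fluctuation var(b) ≈ k_B·T/k_b within 5%, torsion mode within
one 10° histogram bin of the analytic minimum — and (v) 1% convergence of
the SASA operator on a single bead.

Parameter recovery deliberately uses minimal per-term systems (a bonded
dimer, a trimer with one bend, a four-bead chain with one improper or one
torsion): the free monomer is geometrically over-determined (seven bonded
terms against six internal degrees of freedom), so its low-temperature means
sit at the slightly frustrated compromise geometry rather than at the
individual reference values, and exact per-term recovery is only meaningful
where the term is unfrustrated.

The acceptance script samples octamers (n = 8, 32 beads, 80 000 MC steps at
298 K) for gyration-radius and end-to-end statistics — large enough to show
the linkage-dependent ordering of chain extension (β(1→4) most extended,
β(1→3) most compact), small enough to run in minutes on one CPU.  These MC
ensembles are in-vacuo with the synthetic LJ table: they characterize the
bonded model's chain geometry, not solution behaviour; no claim is made of
reproducing solvated-MD averages.

## Known limitations

- No forces/virial for MD integration; the evaluator is energy-only.
- No explicit solvent, pressure coupling or free-energy machinery.
- The synthetic LJ table makes nonbonded-driven observables qualitative.
- Harmonic impropers give single-well ring/backbone geometry: conformational
  "kinks" of long β(1→4) chains are not representable, so chain stiffness of
  long cellulose-like polymers is overestimated by construction.
- Heteropolymers and branching are untested territory and warn accordingly.
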