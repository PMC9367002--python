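# glycocg

A coarse-grained (CG) modelling toolkit for glucopyranose-based carbohydrates,
compatible with the Martini 3 bead taxonomy.  It is aimed at molecular
modellers who want to build, inspect and validate CG models of glucans —
glucose monomers and homopolymer chains joined by the β(1→2), β(1→3),
α(1→4), β(1→4) or α(1→6) glycosidic linkage — without running a full MD
engine.

## The model

Each glucopyranose residue is mapped onto **four beads** placed at the centre
of geometry (COG) of their atom groups (aliphatic hydrogens included):

| bead | region                              | type (default) | size |
|------|-------------------------------------|----------------|------|
| B1   | hydroxymethyl group                 | TP3            | T    |
| B2   | ring oxygen + anomeric carbon       | SN4            | S    |
| B3   | vicinal diol / hydroxyethyl         | P3             | R    |
| B4   | hydroxyethyl                        | TN4            | T    |

The potential energy is a sum of

- bond stretches, V = ½ k_b (b − b₀)²  (GROMACS bonds type 1),
- cosine-harmonic bends, V = ½ k_θ (cos θ − cos θ₀)²  (angles type 2),
- restricted bends, V = ½ k_θ (cos θ − cos θ₀)² / sin² θ  (angles type 10),
  used where θ₀ approaches 180° so the potential diverges at collinearity,
- harmonic impropers, V = ½ k_ξ (ξ − ξ₀)²  (dihedrals type 2),
- periodic torsions, V = k_φ (1 + cos(m φ − φ₀))  (dihedrals type 1),
- 12/6 Lennard-Jones pairs, V = C₁₂/r¹² − C₆/r⁶, shifted to zero at a 1.1 nm
  cutoff, with first covalent neighbours excluded.

All bonded parameters (the monomer table for both anomers plus one table per
linkage type) ship as TSV data files.  Linkage tables are written in
first-linkage bead numbering; the n-th linkage of a chain is obtained by
adding 4n to every bead index, so topologies of arbitrary length are
generated mechanically.  Since the force field describes neutral molecules,
there are no charges.

The package contains, per module:

- `tables` — the parameter registry (term lookup, +4n expansion, LJ pairs);
- `topology` — `ChainSpec` → `Topology` (beads, terms, exclusions);
- `itp` — GROMACS `.itp` writer/reader;
- `coordinates` — COG mapping of atomistic structures, deterministic
  initial-structure generation, `.gro`/`.pdb` I/O;
- `energetics` — per-term energy evaluation with full breakdown;
- `sampling` — Metropolis Monte Carlo over bead coordinates, conformational
  descriptors (bond/angle/torsion statistics, radius of gyration, end-to-end
  distance), torsion histograms, Shrake–Rupley SASA;
- `fixtures` — synthetic atomistic glucans for exercising the mapping;
- `cli` — the `glycocg` command-line tool.

The shipped LJ pair table is a *synthetic* combination-rule construction for
testing the nonbonded machinery (see `src/glycocg/data/lj_pairs_synthetic.tsv`);
supply a calibrated table through the configuration for production use.

## Worked example

Build an α(1→4)-linked octamer (an amylose fragment), generate starting
coordinates and evaluate its energy:

```sh
$ glycocg build-top --linkage a14 --n 8 --anomer beta -o octamer.itp
INFO wrote octamer.itp: 32 beads, 39/58/15/21 terms
$ glycocg build-gro --itp octamer.itp --seed 1 -o octamer.gro
INFO wrote octamer.gro (32 beads)
$ glycocg energy --itp octamer.itp --gro octamer.gro
bond                    0.751262 kJ/mol
angle_g96               2.915457 kJ/mol
angle_restricted        1.546127 kJ/mol
improper                8.074361 kJ/mol
dihedral             -200.587417 kJ/mol
lj                    -90.190589 kJ/mol
total                -277.490799 kJ/mol
```

The octamer carries 4 × 8 = 32 beads and 39 bonds (four ring bonds per
residue plus one glycosidic bond per linkage).  In the relaxed starting
structure the stretch/bend/improper terms sit close to their minima (a few
kJ/mol in total); the torsion total is negative because the α(1→4) torsion
constants are negative, so each torsion at its minimum contributes 2·k_φ < 0.

Sampling and analysis work the same way (`glycocg sample`,
`glycocg descriptors`), and `glycocg fixtures` + `glycocg map-aa` demonstrate
the atomistic-to-CG mapping on a synthetic glucan.  The same functionality is
available from Python:

```python
from glycocg import ChainSpec, build_topology, generate_initial_coords, total_energy

top = build_topology(ChainSpec(n_residues=8, linkage="a14"))
conf = generate_initial_coords(top, seed=1)
print(total_energy(top, conf).as_dict())
```

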