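# ffport

Automated, reproducible porting of CHARMM-additive-format force-field files
(topology `*.rtf`, parameter `*.prm`, stream `*.str`) into a complete
GROMACS-format force-field directory — including the auxiliary databases the
CHARMM files do not contain (chain termini, hydrogen addition), which are
synthesized heuristically from bonded connectivity — plus an internal
dual-functional-form energy oracle that proves the converted parameters are
energetically equivalent to the originals.

It is written for force-field maintainers and simulation practitioners who
need a CHARMM-family force field (protein, nucleic acid, carbohydrate,
lipid, CGenFF) usable with GROMACS's `pdb2gmx`/`grompp` toolchain without
hand-editing thousands of parameter lines.

## What the conversion actually does

**Units and functional forms.** CHARMM works in AKMA units (Å, kcal/mol) and
writes harmonic terms as `V = K (x − x₀)²`; GROMACS works in nm and kJ/mol
and writes `V = ½ k (x − x₀)²`. Hence every harmonic force constant picks up
a factor of 2 on top of the unit factors (4.184 kJ/kcal exactly, 100 nm⁻²
per Å⁻² for length-based terms). Periodic dihedrals
`V = K_χ (1 + cos(nχ − δ))` have the same form in both codes and get no
factor of 2. Lennard-Jones parameters convert from (ε, R_min/2) to (σ, ε)
via `R_min = 2^{1/6} σ`; pair-specific overrides (NBFIX) list the full
R_min. CHARMM's dedicated 1–4 Lennard-Jones sets (it never scales 1–4
interactions) become explicit `pairtypes` entries; CMAP grids scale
elementwise.

**Geometry perception.** The CHARMM files carry no angles, dihedrals, or 3-D
recipes that GROMACS's topology builder could reuse (internal-coordinate
tables are discarded). `ffport` derives what it needs from the *bonded
tree*: a breadth-first expansion of the bond graph from each atom, avoiding
rings, whose depth-2 and depth-3 simple paths are exactly the valence angles
and proper dihedrals (reversed duplicates discarded). For chainable residues
an infinite homopolymer is assumed, so junction-crossing terms (`-C N CA`…)
are enumerated too. Attaching equilibrium values from the parameter tables
to these paths approximates the internal geometry well enough to classify
every hydrogen-bearing center (planar / tetrahedral / linear / threefold)
and thereby to generate hydrogen-addition rules and termini entries.

**Patching.** CHARMM `PRES` patches are applied to base residues to mint
standalone residue definitions, split in half for two-residue cross-links
(disulfides), or diffed against their base to produce the ordered
`[delete]` / `[replace]` / `[add]` directives of a GROMACS termini-database
entry. Atom identity is by name: a renamed atom is a deletion plus an
addition.

**Fixups.** Two engine differences require repairs: dihedrals spanning a
180° valence angle are geometrically undefined and deliberately
unparameterized upstream (the conversion adds zero-force dummy types so the
downstream grompp check passes), and impropers declared with a permuted
non-central atom order get their parameter replicated under the declared
order. Both land in a separate `ffmissingdihedrals.itp`.

**Validation.** Two independent single-point evaluators — one implementing
the CHARMM functional forms on the original tables, one the GROMACS forms on
the converted set — score identical configurations in vacuum with no
cutoffs. Exact conversion implies `E_kJ = 4.184 · E_kcal` per term; the
shipped validation battery verifies this to ~10⁻¹⁴ relative (tolerance
10⁻⁹) across bond, angle, Urey–Bradley, proper, improper, LJ, 1–4 LJ,
Coulomb and CMAP terms.

## Worked example

The package ships a synthetic toy force-field generator so every stage runs
without any external download:

```sh
ffport fixture --seed 1 --size 10 -o fixture   # CHARMM-format toy files
ffport convert fixture/ffport.in -o port       # write port/toyff.ff/
ffport validate fixture/ffport.in --seed 3     # energy equivalence
```

`ffport validate` prints one line per test configuration, e.g.:

```
ALX#0                    worst rel. diff 4.418e-15 (lj) ok
BTY#0                    worst rel. diff 1.928e-14 (bond) ok
SOD+ETX#0                worst rel. diff 1.688e-14 (bond) ok
...
PASS
```

Each line is one configuration (residue, replica index); the number is the
largest per-term relative difference between the two evaluators after
putting both energies on the kJ/mol scale — parameter conversion is exact,
so only floating-point round-off (~10⁻¹⁴) remains. `ffport convert` reports
the repairs it made:

```
dummy dihedral types: [('CT', 'CY', 'CY', 'CT')]
replicated impropers: [('HG', 'CG', 'CG', 'NG')]
```

the first being the torsion across the toy alkyne's triple bond (undefined
at the 180° angle, emitted with zero force constant), the second an improper
whose parameter only existed under a permuted atom order.

The same steps are available as library calls; see `examples/` for short
narrative scripts (parsing/conversion, geometry perception, patching and
termini, hydrogen database, energy equivalence, full port).

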