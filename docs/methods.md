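# Methods

This note documents the models, heuristics, numeric conventions and design
choices behind `ffport`, and what the synthetic test battery does and does
not demonstrate about real force-field releases.

## Parameter conversion

All conversions are exact arithmetic, never fits or rounding:

| quantity | CHARMM | GROMACS | rule |
|---|---|---|---|
| harmonic bond / UB | K (kcal mol⁻¹ Å⁻²), x₀ (Å) | k (kJ mol⁻¹ nm⁻²), x₀ (nm) | k = 2·K·4.184·100; x₀/10 |
| harmonic angle / improper | K (kcal mol⁻¹ rad⁻²), θ₀ (deg) | k (kJ mol⁻¹ rad⁻²), θ₀ (deg) | k = 2·K·4.184; θ₀ unchanged |
| periodic dihedral | K_χ (kcal mol⁻¹), n, δ | same form | K·4.184; no factor 2 |
| Lennard-Jones | ε (printed negative), R_min/2 (Å) | σ (nm), ε (kJ mol⁻¹) | σ = 2·(R_min/2)/2^{1/6}/10; ε = \|ε\|·4.184 |
| NBFIX | ε, full R_min (Å) | σ, ε | σ = R_min/2^{1/6}/10 |
| CMAP | kcal mol⁻¹ grid | kJ mol⁻¹ grid | elementwise ×4.184 |

Conventions: the thermochemical calorie (4.184 exactly); equilibrium angles
stay in degrees while angular force constants are per rad² (the downstream
file convention — the asymmetry is deliberate); printed-positive ε values
draw a warning but are used as magnitudes; the CHARMM wildcard `X` is kept
internally and written with the downstream wildcard token (also `X`).
Conversion is invertible to 1e-12 relative and preserves entry counts per
category.

1–4 pairs: CHARMM substitutes a second LJ set rather than scaling, so both
1–4 scaling factors in the written `[defaults]` block are 1.0 and pair
parameters are enumerated explicitly. By default only pairs in which at
least one type carries a dedicated 1–4 set are written (the rest are covered
by the writer's `gen-pairs` declaration under Lorentz–Berthelot rules); a
config switch (`pairtypes full`) enumerates all N(N+1)/2 pairs instead,
since upstream practice does not dictate one mode.

## Geometry perception

The bonded tree expands breadth-first from a root atom through declared
bonds; a child equal to any ancestor *on its own path* is pruned (simple
paths — a global visited set would miss fused-ring angles). Depth-2 paths
are valence angles, depth-3 paths proper dihedrals, deduplicated under
reversal. The implementation is checked against exhaustive simple-path
enumeration on random graphs.

Chain closure: a residue is treated as homopolymer-chainable iff every
`+`/`-`-prefixed bond partner also exists unprefixed in the residue itself
(amino acids declaring `-C N`, nucleotides declaring `-O3' P`, …). Terms
crossing the junction are enumerated on a five-copy polymer graph and
canonicalized by shifting so that the representation maximizes unprefixed
atoms, preferring the `-` side on ties — making the result independent of
which side the junction was walked from. Residues with prefixed bonds whose
partner is absent (caps) are closed against every chainable residue of the
same class; the union of terms is kept and type conflicts across partners
warn and keep the first value.

Center classification runs a fixed cascade (first hit wins): (1) improper
centered on the atom with a 0°/180° minimum → planar; (2) any incident
angle with θ₀ ≥ 175° → linear; (3) dominant proper multiplicity around the
atom's bonds: n=3 → threefold, n=2 with δ=180° → planar; (4) mean incident
θ₀ within ±8° of 109.5° → tetrahedral, of 120° → planar; (5) tetrahedral
with a warning. The 175° and ±8° thresholds, and the cascade order itself,
are this package's choices (config-overridable via `collinearity` and
`planaritytol`); the criteria admit no unique precedence and near-linear
perceived angles must still count as linear.

## Patching and termini

`apply_patch` deletes first (atom plus every bonded record touching it),
then replaces same-named atoms in place or appends new ones in patch order,
then appends patch bonds/impropers/CMAPs with deduplication; total charge is
recomputed. Two-residue patches are split by the `1`/`2` name selectors;
the single inter-residue linking bond is dropped from both halves — its
reconstruction belongs to the engine-global special-bond table, not the
residue definition.

Termini entries are the diff between base and patched residue expressed as
directives, emitted in delete → replace → add → impropers order with no
atom in two directives: explicit deletions; type/charge edits as replaces
(renames decompose into delete+add because identity is by name); additions
grouped per attachment center and name stem, carrying the addition-rule
code and control atoms of that center; deletions of atoms added by *other
same-side* termini; and deletions of configured stray terminal atoms (e.g.
`OXT`). "Other termini" is scoped per side because an N-terminus will never
encounter a C-terminal atom at the chain start. If a patch edits different
base residues differently, per-residue variant entries are emitted with a
warning. Re-applying a generated entry to its base reproduces the patched
atoms, types and charges exactly (modulo the cross-terminus/stray
deletions); atom *positions* are explicitly not a contract — the
delete-then-re-add strategy perturbs some coordinates, which a short
minimization resolves downstream.

## Hydrogen database

Hydrogens (mass < 3.5 u) are grouped by bonded heavy atom; the rule code
follows from the center classification, hydrogen count and heavy-neighbor
count (1 planar H → 1; 2 planar H → 3; 3 tetrahedral H → 4; 1 tetrahedral
H with 3 heavy neighbors → 5; 2 tetrahedral H with 2 heavy neighbors → 6;
a rotatable single H, e.g. hydroxyl, and hydrogens on linear centers →
dihedral-defined rule 2). Control atoms are the center followed by the
nearest heavy neighbors by tree depth, ties broken heavier-first then
alphabetically; hydrogens are used only as a last resort (ethane-sized
molecules have no third heavy atom), and chain-prefixed controls are
allowed. Every block carries exactly three control atoms — a uniform
convention of this package (the downstream engine's rule 5 traditionally
lists a fourth). Unclassifiable centers, stem mismatches (hydrogens of one
group must be `stem+1..n`) and control-atom shortages route the residue
into a manual-attention report instead of silently wrong output. Water
residues are excluded (dedicated rigid topologies cover them); lone-pair /
virtual-site residues are excluded from the entire port because the
downstream topology builder cannot construct such sites.

## Fixups

A dihedral whose internal valence angle has θ₀ at or above the
collinearity threshold (default 175°, config-overridable; perceived values
may be near- rather than exactly linear) and no parameter gets a dummy type
with k=0, n=1, δ=0 — any values are force-free at k=0, these are the
simplest. Unparameterized non-collinear dihedrals are hard errors. Improper
terms matching no parameter under the declared order (or its reverse, or
outer-position wildcards) are retried under all permutations of the three
non-central atoms; the first hit in canonical permutation order is
replicated under the declared order, all hits are logged, duplicates by key
deduplicated. Both repairs go to `ffmissingdihedrals.itp`, included from
`forcefield.itp`, keeping provenance separate from the pristine converted
tables. All retained residues are scanned, not only those requested in a
user topology. After fixups a completeness check asserts every enumerated
bonded term has a parameter.

## Writers

Output is deterministic (stable orderings, fixed formats): parameters are
printed with shortest-round-trip float formatting so the written
`ffbonded`/`ffnonbonded`/`nbfix` files re-parse into exactly the converted
parameter set (a fixed 6-significant-digit format would break this for
derived σ values); charges use a fixed `%.3f`. Atom 1–4 overrides ride
along as structured comments on the `[atomtypes]` lines so the round trip
covers them too. Residues are written per residue class (one `.rtp` per
class, preserving the upstream organization and charge groups, which the
downstream engine parses but ignores); copyresidue aliases appear as full
duplicate entries under both names; DONOR/ACCEPTOR/IC content and bond
orders are absent by construction. Referential integrity (every used atom
type declared) is checked before any file is written.

Water models are engine-side conventions rather than force-field data, so
their literature constants (original and CHARMM-modified TIP3P, SPC, SPC/E,
TIP4P, TIP4P-Ew, TIP5P) live in the porting code and are emitted as rigid
3/4/5-site topologies with their own atom types; the CHARMM-modified TIP3P
(with LJ sites on the hydrogens) is the default, being the model the
force-field family is calibrated against.

## Energy oracle

Two independent evaluators share one configuration (coordinates in Å on one
side, the same ×0.1 in nm on the other): CHARMM forms on the original
tables, GROMACS forms on the converted set. Evaluation is vacuum-only with
no cutoffs, which by construction removes the neighbor-list/cutoff
discrepancies that dominate condensed-phase cross-engine comparisons;
exclusions are 1-2/1-3, pairs 1-4. Both evaluators use the same electric
conversion factor (138.935458 kJ mol⁻¹ nm e⁻², i.e. 332.0637 in the AKMA
frame) rather than CHARMM's historical rounded 332.0716, so the Coulomb
term satisfies the exact ×4.184 identity; the discrepancy between the two
constants (~3×10⁻⁵ relative) is far below any cross-engine agreement one
would measure in practice. CMAP is interpolated bilinearly in both
evaluators; because conversion is a pure scaling, the equivalence identity
holds for any interpolant as long as both sides use the same one. Both
evaluators emulate the source engine's tolerance for permuted improper atom
orders so they remain comparable before and after fixups.

## Synthetic fixture generator

`generate_fixture_ff(seed, size)` emits 2–10 residues of deterministic,
syntactically complete CHARMM-format text: chainable amino-acid-like
residues with junction bonds, impropers and a backbone CMAP; a capped
dipeptide whose CMAP lies entirely inside the residue (so the grid term is
exercised in single-molecule energies); ethanol (hydroxyl rule, wildcard
torsion); 2-butyne (exactly one collinear dihedral class left
unparameterized — a terminal alkyne would produce two); a planar fragment
declaring its improper in a permuted order; a lone-pair residue; a sodium
ion with NBFIX overrides against hydroxyl/carboxylate oxygens (the ion is
paired with an oxygen-bearing molecule in the validation battery so the
override path is scored); and filler alkanes. Numeric values are drawn per
seed from ranges typical of additive biomolecular force fields; equilibrium
angles are fixed by chemistry (180° sp, ~120° sp², ~109.5° sp³, jitter kept
well inside the ±8° classification bands). Parameter coverage is guaranteed
by running the converter's own term enumeration at generation time — except
the deliberate collinear hole.

Test configurations are built from the perceived geometry by NeRF-style
breadth-first placement: bond lengths and angles from the parameter tables
with ~4% jitter (so every term is strictly positive), random torsions,
collinear angles bent to 178° to keep torsion placement defined. These are
plausible, not minimized, structures — sufficient because both evaluators
see the identical geometry.

What passing does and does not show: the battery proves the *conversion
arithmetic and bookkeeping* (term enumeration, exclusion lists, override
precedence, fixups) are exact on structurally complete but small inputs. It
does not exercise the full released force fields' scale, their IC-built
reference geometries, condensed-phase cutoff effects, or engine
implementation details — cross-engine agreement on those requires running
the engines themselves, which is outside this package's scope.

## Problem sizes

Defaults keep everything interactive: fixture size 10 residues (~10–18
atoms each), ≥20 validation configurations (two replicas of every
multi-atom residue plus ion pairs), 200 random graphs of ≤12 nodes for the
enumeration oracle, 8×8 CMAP grids (45° spacing — structurally faithful,
compact). The full test suite runs in a few seconds on one CPU.

## Known limitations

- No execution of CHARMM scripting (GENERATE/PATCH at runtime), no PSF
  reading or writing, no engine runs, no trajectory work.
- Lone-pair/virtual-site residues are dropped, not ported.
- Acetyl/N-methylamide-style caps are handled as standalone residues, not
  termini entries, mirroring downstream-builder limitations.
- The conversion-control file schema is this package's own format (keyword
  per line, `#` comments); there is no published normative schema to match.
- The termini machinery guarantees topology, not coordinates.
- hdb rule selection covers the six standard geometric recipes; exotic
  centers (e.g. five-coordinate) fall into the manual-attention report.
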