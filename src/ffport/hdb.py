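"""Hydrogen-addition database generation.

The topology builder downstream can reconstruct missing hydrogens if it knows,
for every hydrogen group, an addition rule (a small integer mapping to an
internal-geometry recipe) and control atoms that anchor the construction.
None of this exists in the source force field; it is synthesized here from the
perceived local geometry: the classification of the bonded heavy atom, the
number of hydrogens it carries and the number of its heavy neighbors select
the rule, and the nearest heavy neighbors by bond depth become the control
atoms.

Rule codes follow the downstream engine's documented set:

===  =========================================== =========================
code meaning                                     selected when
===  =========================================== =========================
1    one planar hydrogen                         planar center, 1 H
2    one single hydrogen, dihedral-defined       1 H on a center with one
                                                 heavy neighbor (hydroxyl,
                                                 thiol) or a linear center
3    two planar hydrogens                        planar center, 2 H
4    three tetrahedral hydrogens                 tetrahedral center, 3 H
5    one tetrahedral hydrogen                    tetrahedral center, 1 H,
                                                 3 heavy neighbors
6    two tetrahedral hydrogens                   tetrahedral center, 2 H,
                                                 2 heavy neighbors
===  =========================================== =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .geometry import (
    LINEAR,
    PLANAR,
    TETRAHEDRAL,
    THREEFOLD,
    PerceivedGeometry,
    adjacency_from_bonds,
    build_tree,
)
from .model import (
    ForceFieldSource,
    ResidueTopology,
    is_chain_prefixed,
    strip_chain_prefix,
)
from .units import HYDROGEN_MASS_CUTOFF


@dataclass
class HAddBlock:
    h_count: int
    rule_code: int
    name_stem: str
    control_atoms: tuple[str, str, str]


@dataclass
class HAddRule:
    residue: str
    blocks: list[HAddBlock] = field(default_factory=list)


@dataclass
class AttentionItem:
    residue: str
    atom: str
    reason: str


def select_rule(
    center_class: str, n_added: int, n_heavy: int
) -> Optional[int]:
    """Addition-rule code from the center classification, the number of
    atoms to construct on it and its heavy-neighbor count; None if the
    combination has no recipe."""
    if n_added == 1 and n_heavy == 1 and center_class != PLANAR:
        return 2  # freely rotatable single atom (hydroxyl-like)
    if center_class == LINEAR:
        return 2 if n_added == 1 else None
    if center_class == PLANAR:
        if n_added == 1:
            return 1
        if n_added == 2:
            return 3
        return None
    if center_class in (TETRAHEDRAL, THREEFOLD):
        if n_added == 3:
            return 4
        if n_added == 2 and n_heavy == 2:
            return 6
        if n_added == 1 and n_heavy == 3:
            return 5
        # a lone H on a 2-heavy-neighbor sp3 center is still constructible
        # as a dihedral-defined single atom
        if n_added == 1:
            return 2
    return None


def _atom_mass(name: str, residue: ResidueTopology, source: ForceFieldSource) -> float:
    base = strip_chain_prefix(name)
    if residue.has_atom(base):
        t = residue.atom(base).type
        m = source.params.masses.get(t)
        return m.mass if m else 0.0
    return 0.0


def is_water(residue: ResidueTopology, source: ForceFieldSource) -> bool:
    heavy = [
        a
        for a in residue.atoms
        if (m := source.params.masses.get(a.type)) is None
        or m.mass >= HYDROGEN_MASS_CUTOFF
    ]
    light = [a for a in residue.atoms if a not in heavy]
    return (
        len(heavy) == 1
        and len(light) == 2
        and 14.0 < source.params.masses[heavy[0].type].mass < 18.5
    )


def control_atoms_for(
    center: str,
    residue: ResidueTopology,
    source: ForceFieldSource,
    geom: PerceivedGeometry,
    exclude: Optional[set[str]] = None,
) -> Optional[tuple[str, str, str]]:
    """Three control atoms: the center itself, then the nearest heavy
    neighbors by bonded-tree depth; ties broken heavier-first, then
    alphabetically.  Chain-prefixed atoms are allowed.  ``exclude`` names
    (e.g. atoms being added) never become controls."""
    exclude = exclude or set()
    # adjacency over declared bonds; prefixed names are literal leaf nodes
    bonds = []
    for a, b in residue.bonds:
        if strip_chain_prefix(a) in exclude or strip_chain_prefix(b) in exclude:
            continue
        bonds.append((a, b))
    if not any(center in bond for bond in bonds):
        return None
    adj = adjacency_from_bonds(bonds)
    tree = build_tree(adj, center, max_depth=3)
    heavy_tiers: list[list[tuple[float, str]]] = []
    hydrogen_tiers: list[list[tuple[float, str]]] = []
    for depth, layer in enumerate(tree.layers):
        if depth == 0:
            continue
        heavy: list[tuple[float, str]] = []
        light: list[tuple[float, str]] = []
        for atom, _parent in layer:
            name = str(atom)
            if strip_chain_prefix(name) in exclude:
                continue
            mass = _atom_mass(name, residue, source)
            is_h = not is_chain_prefixed(name) and mass < HYDROGEN_MASS_CUTOFF
            (light if is_h else heavy).append((-mass, name))
        heavy_tiers.append(sorted(heavy))
        hydrogen_tiers.append(sorted(light))
    chosen: list[str] = [center]
    # nearest heavy neighbors first; hydrogens only as a last resort
    # (small molecules like ethane have no third heavy atom to anchor on)
    for tiers in (heavy_tiers, hydrogen_tiers):
        for tier in tiers:
            for _negmass, name in tier:
                if name not in chosen:
                    chosen.append(name)
                if len(chosen) == 3:
                    return tuple(chosen)  # type: ignore[return-value]
    return None


def _stem(names: list[str]) -> Optional[str]:
    stems = {n.rstrip("0123456789") for n in names}
    if len(stems) != 1:
        return None
    return stems.pop()


def generate_hdb(
    residue: ResidueTopology,
    geom: PerceivedGeometry,
    source: ForceFieldSource,
) -> tuple[HAddRule, list[AttentionItem]]:
    """Hydrogen-addition blocks for one residue.

    Every hydrogen lands in exactly one block or in the manual-attention
    report; blocks are emitted in the order the heavy atoms appear in the
    residue.  Deterministic and invariant to the ordering of the declared
    bonds (neighbors are re-sorted internally).
    """
    rule = HAddRule(residue=residue.name)
    attention: list[AttentionItem] = []
    if is_water(residue, source):
        return rule, attention  # water is handled by dedicated topologies
    for atom in residue.atoms:
        center = atom.name
        hs = sorted(geom.hydrogens.get(center, ()))
        if not hs:
            continue
        cls = geom.classification.get(center)
        heavies = geom.heavy_neighbors.get(center, [])
        code = select_rule(cls or "", len(hs), len(heavies)) if cls else None
        stem = _stem(hs) if len(hs) > 1 else hs[0]
        controls = control_atoms_for(
            center, residue, source, geom, exclude=set(hs)
        )
        if code is None or controls is None or stem is None:
            reason = (
                "no addition rule for this center"
                if code is None
                else "no common name stem" if stem is None else "too few control atoms"
            )
            attention.append(AttentionItem(residue.name, center, reason))
            continue
        if len(hs) > 1:
            expected = {f"{stem}{i}" for i in range(1, len(hs) + 1)}
            if set(hs) != expected:
                attention.append(
                    AttentionItem(
                        residue.name, center, "hydrogen names are not stem+1..n"
                    )
                )
                continue
        rule.blocks.append(HAddBlock(len(hs), code, stem, controls))
    return rule, attention
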