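"""Applying PRES patches and deriving termini-database entries.

Patches serve three distinct purposes here:

* minting standalone residues (protonation states, methylations, deoxy
  sugars): :func:`apply_patch`;
* cross-links that edit two residues at once (disulfide-style): split into
  half-patches with :func:`split_crosslink_patch`, each half then applied as
  an ordinary patch (the inter-residue bond itself is the business of the
  engine-global special-bond table, not of the residue definition);
* chain termini: translated into an ordered list of delete / replace / add
  directives by :func:`build_terminus_entry`.

Atom identity is by name only: an atom whose name changes is a deletion plus
an addition, never a rename.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Union

from .geometry import classify_center, perceive_residue
from .hdb import control_atoms_for, select_rule
from .model import (
    AtomRecord,
    FFError,
    ForceFieldSource,
    ParameterTables,
    PatchTopology,
    ResidueTopology,
    is_chain_prefixed,
    strip_chain_prefix,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# patch application
# ---------------------------------------------------------------------------


def _same_bond(x: tuple[str, str], y: tuple[str, str]) -> bool:
    return x == y or x == (y[1], y[0])


def _same_quad(x: Sequence[str], y: Sequence[str]) -> bool:
    return tuple(x) == tuple(y) or tuple(x) == tuple(reversed(y))


def apply_patch(
    base: ResidueTopology, patch: PatchTopology, new_name: str
) -> ResidueTopology:
    """Mint a standalone residue by mapping a single-residue patch onto a
    base residue.

    Deletions go first (the atom and every bonded record touching it), then
    patch atoms replace same-named atoms in place or are appended in patch
    order; patch bonds/impropers/cmaps are appended with deduplication.
    """
    if patch.two_residue:
        raise FFError(
            f"patch {patch.name} edits two residues; split it first"
        )
    res = base.copy(name=new_name)
    res.source = f"{base.source}+{patch.source}"
    res.annotations.append(f"patched: {base.name} + {patch.name}")

    for name in patch.deleted_atoms:
        if not res.has_atom(name):
            raise FFError(
                f"patch {patch.name}: cannot delete nonexistent atom {name!r} "
                f"of {base.name}"
            )
        res.atoms = [a for a in res.atoms if a.name != name]
        res.bonds = [b for b in res.bonds if name not in b]
        res.impropers = [q for q in res.impropers if name not in q]
        res.cmaps = [c for c in res.cmaps if name not in c]

    max_group = max((a.group_index for a in res.atoms), default=-1)
    for patom in patch.atoms:
        if res.has_atom(patom.name):
            target = res.atom(patom.name)
            target.type = patom.type
            target.charge = patom.charge  # position and group kept
        else:
            res.atoms.append(
                AtomRecord(
                    patom.name, patom.type, patom.charge,
                    max_group + 1 + patom.group_index,
                )
            )

    for quad in patch.deleted_impropers:
        res.impropers = [q for q in res.impropers if not _same_quad(q, quad)]

    for bond in patch.bonds:
        if not any(_same_bond(bond, b) for b in res.bonds):
            res.bonds.append(bond)
    for quad in patch.impropers:
        if not any(_same_quad(quad, q) for q in res.impropers):
            res.impropers.append(quad)
    for octet in patch.cmaps:
        if not any(_same_quad(octet, c) for c in res.cmaps):
            res.cmaps.append(octet)

    known = set(res.atom_names)
    for a, b in res.bonds:
        for x in (a, b):
            if not is_chain_prefixed(x) and x not in known:
                raise FFError(
                    f"patch {patch.name} on {base.name}: dangling bond atom {x!r}"
                )
    res.total_charge = res.charge_sum()
    from .charmm_io import _residue_is_chainable

    res.chainable = _residue_is_chainable(res)
    return res


def split_crosslink_patch(patch: PatchTopology, side: int) -> PatchTopology:
    """One half of a two-residue patch: keep the atoms/edits whose ``1``/``2``
    selector matches ``side``, strip the selectors, drop cross-side terms.

    The single linking bond between the partners is dropped from both halves;
    reconstructing it at topology-build time is the job of the engine's
    special-bond mechanism."""
    if not patch.two_residue:
        raise FFError(f"patch {patch.name} is not a two-residue patch")
    if side not in (1, 2):
        raise FFError("side must be 1 or 2")
    sel = str(side)

    def mine(name: str) -> bool:
        return name[:1] == sel

    def strip(name: str) -> str:
        return name[1:] if name[:1] in "12" else name

    half = PatchTopology(
        name=f"{patch.name}_{side}",
        total_charge=0.0,
        source=patch.source,
    )
    for a in patch.atoms:
        if mine(a.name):
            half.atoms.append(
                AtomRecord(strip(a.name), a.type, a.charge, a.group_index)
            )
    half.deleted_atoms = [strip(n) for n in patch.deleted_atoms if mine(n)]

    cross_bonds = 0
    for a, b in patch.bonds:
        sides = {a[:1], b[:1]}
        if sides == {sel}:
            half.bonds.append((strip(a), strip(b)))
        elif len(sides & {"1", "2"}) == 2:
            cross_bonds += 1
            log.info(
                "patch %s: linking bond %s-%s left to the special-bond table",
                patch.name, a, b,
            )
    for seq, target in (
        (patch.impropers, half.impropers),
        (patch.deleted_impropers, half.deleted_impropers),
    ):
        for quad in seq:
            sides = {n[:1] for n in quad} & {"1", "2"}
            if sides == {sel}:
                target.append(tuple(strip(n) for n in quad))  # type: ignore[arg-type]
            elif len(sides) == 2:
                log.warning(
                    "patch %s: improper %s mixes both residues; dropped",
                    patch.name, quad,
                )
    for octet in patch.cmaps:
        sides = {n[:1] for n in octet} & {"1", "2"}
        if sides == {sel}:
            half.cmaps.append(tuple(strip(n) for n in octet))
        elif len(sides) == 2:
            log.warning(
                "patch %s: CMAP %s mixes both residues; dropped", patch.name, octet
            )
    half.total_charge = float(sum(a.charge for a in half.atoms))
    half.two_residue = False
    return half


# ---------------------------------------------------------------------------
# termini database entries
# ---------------------------------------------------------------------------


@dataclass
class Delete:
    atom: str


@dataclass
class Replace:
    atom: str
    new_type: str
    new_mass: float
    new_charge: float


@dataclass
class Add:
    count: int
    name_stem: str
    rule_code: int
    control_atoms: tuple[str, str, str]
    new_type: str
    new_mass: float
    new_charge: float


@dataclass
class ImproperAdd:
    quad: tuple[str, str, str, str]


Directive = Union[Delete, Replace, Add, ImproperAdd]


@dataclass
class TerminusEntry:
    name: str
    directives: list[Directive] = field(default_factory=list)

    def directive_atoms(self) -> set[str]:
        out: set[str] = set()
        for d in self.directives:
            if isinstance(d, (Delete, Replace)):
                out.add(d.atom)
            elif isinstance(d, Add):
                if d.count == 1:
                    out.add(d.name_stem)
                else:
                    out.update(f"{d.name_stem}{i}" for i in range(1, d.count + 1))
        return out


def _mass_of(type_name: str, params: ParameterTables) -> float:
    m = params.masses.get(type_name)
    return m.mass if m else 0.0


def _added_atom_names(patch: PatchTopology, base: ResidueTopology) -> list[str]:
    return [a.name for a in patch.atoms if not base.has_atom(a.name)]


def _group_additions(
    names: list[str], patched: ResidueTopology
) -> list[list[str]]:
    """Group added atoms by (attachment atom, digit-stripped stem, type,
    charge); groups that cannot share an add directive stay separate."""
    info: dict[str, tuple[str, str, str, float]] = {}
    adj: dict[str, list[str]] = {a.name: [] for a in patched.atoms}
    for a, b in patched.bonds:
        for x, y in ((a, b), (b, a)):
            if not is_chain_prefixed(x) and x in adj:
                adj[x].append(y)
    added = set(names)
    for n in names:
        anchors = [strip_chain_prefix(x) for x in adj.get(n, []) if strip_chain_prefix(x) not in added]
        anchor = anchors[0] if anchors else ""
        atom = patched.atom(n)
        info[n] = (anchor, n.rstrip("0123456789"), atom.type, atom.charge)
    groups: dict[tuple, list[str]] = {}
    for n in names:
        groups.setdefault(info[n], []).append(n)
    # groups of size > 1 must be named stem+1..n to be expandable
    out: list[list[str]] = []
    for key, members in groups.items():
        if len(members) == 1:
            out.append(members)
            continue
        stem = key[1]
        expected = [f"{stem}{i}" for i in range(1, len(members) + 1)]
        if sorted(members) == sorted(expected):
            out.append(sorted(members, key=expected.index))
        else:
            out.extend([m] for m in members)
    return out


def build_terminus_entry(
    patch: PatchTopology,
    side: str,
    base_residues: list[ResidueTopology],
    all_termini_patches: list[PatchTopology],
    extra_deletes: list[str],
    source: ForceFieldSource,
) -> tuple[list[TerminusEntry], list[str]]:
    """Terminus-database entries for one patch.

    Directive generation follows five rules, in order: (1) atoms the patch
    explicitly deletes -> delete; (2) atoms it modifies -> replace when only
    type/charge change (a name change is a delete plus an add by
    construction); (3) atoms it adds -> add directives carrying the rule code
    and control atoms of the attachment center; (4) atoms added by *other*
    termini of the same side -> delete; (5) the configured frequently
    appearing terminal atoms (e.g. OXT) -> delete.  No atom ever appears in
    two directives.

    If the patch edits all base residues identically one entry is returned;
    otherwise one per-residue variant entry is emitted per base, with a
    warning in the second return value.
    """
    if not base_residues:
        raise FFError(f"terminus patch {patch.name}: no base residues to apply to")
    params = source.params
    warnings: list[str] = []
    per_base: list[TerminusEntry] = []
    for base in base_residues:
        entry = TerminusEntry(name=patch.name)
        covered: set[str] = set()

        def claim(atom: str) -> bool:
            if atom in covered:
                return False
            covered.add(atom)
            return True

        patched = apply_patch(base, patch, f"{base.name}_{patch.name}")
        geom = perceive_residue(patched, source)

        # rule 1: explicit deletions
        for name in patch.deleted_atoms:
            if claim(name):
                entry.directives.append(Delete(name))
        # rule 2: modifications of surviving base atoms
        for patom in patch.atoms:
            if not base.has_atom(patom.name):
                continue
            old = base.atom(patom.name)
            if (old.type, old.charge) != (patom.type, patom.charge):
                if claim(patom.name):
                    entry.directives.append(
                        Replace(
                            patom.name, patom.type,
                            _mass_of(patom.type, params), patom.charge,
                        )
                    )
        # rule 3: additions, grouped per attachment center
        added = _added_atom_names(patch, base)
        for group in _group_additions(added, patched):
            first = patched.atom(group[0])
            anchors = [
                strip_chain_prefix(x)
                for a, b in patched.bonds
                for x, y in ((a, b), (b, a))
                if strip_chain_prefix(y) == group[0]
            ]
            anchor = next((a for a in anchors if a not in added), None)
            if anchor is None:
                warnings.append(
                    f"{patch.name}: added atom {group[0]} has no anchor in "
                    f"{base.name}; skipped"
                )
                continue
            cls = geom.classification.get(anchor)
            if cls is None:
                cls = classify_center(anchor, geom)
            n_heavy = len(
                [
                    x
                    for x in geom.heavy_neighbors.get(anchor, [])
                    if strip_chain_prefix(x) not in added
                ]
            )
            code = select_rule(cls, len(group), n_heavy)
            controls = control_atoms_for(
                anchor, patched, source, geom, exclude=set(added)
            )
            if code is None or controls is None:
                warnings.append(
                    f"{patch.name}: no addition rule for {group} on {anchor} "
                    f"({cls}); manual attention"
                )
                continue
            stem = group[0] if len(group) == 1 else group[0].rstrip("0123456789")
            for name in group:
                claim(name)
            entry.directives.append(
                Add(
                    len(group), stem, code, controls,
                    first.type, _mass_of(first.type, params), first.charge,
                )
            )
        # rule 4: atoms other same-side termini add, absent here
        for other in all_termini_patches:
            if other.name == patch.name:
                continue
            for name in _added_atom_names(other, base):
                if not patched.has_atom(name) and claim(name):
                    entry.directives.append(Delete(name))
        # rule 5: frequently appearing terminal atoms
        for name in extra_deletes:
            if not patched.has_atom(name) and claim(name):
                entry.directives.append(Delete(name))
        # new impropers introduced by the patch
        for quad in patch.impropers:
            if not any(_same_quad(quad, q) for q in base.impropers):
                entry.directives.append(ImproperAdd(tuple(quad)))  # type: ignore[arg-type]
        # canonical order: delete, replace, add, impropers
        order = {Delete: 0, Replace: 1, Add: 2, ImproperAdd: 3}
        entry.directives.sort(key=lambda d: order[type(d)])
        per_base.append(entry)

    first = per_base[0]
    if all(e.directives == first.directives for e in per_base[1:]):
        return [first], warnings
    warnings.append(
        f"terminus patch {patch.name}: edits differ across base residues; "
        "emitting per-residue variants"
    )
    for entry, base in zip(per_base, base_residues):
        entry.name = f"{patch.name}-{base.name}"
    return per_base, warnings


def apply_terminus_entry(
    entry: TerminusEntry, base: ResidueTopology, params: ParameterTables
) -> ResidueTopology:
    """Re-apply a generated terminus entry to its base residue (the round-trip
    used to prove the directives reproduce the patched topology)."""
    res = base.copy(name=f"{base.name}_{entry.name}")
    for d in entry.directives:
        if isinstance(d, Delete):
            if res.has_atom(d.atom):
                res.atoms = [a for a in res.atoms if a.name != d.atom]
                res.bonds = [b for b in res.bonds if d.atom not in b]
                res.impropers = [q for q in res.impropers if d.atom not in q]
                res.cmaps = [c for c in res.cmaps if d.atom not in c]
        elif isinstance(d, Replace):
            target = res.atom(d.atom)
            target.type = d.new_type
            target.charge = d.new_charge
        elif isinstance(d, Add):
            names = (
                [d.name_stem]
                if d.count == 1
                else [f"{d.name_stem}{i}" for i in range(1, d.count + 1)]
            )
            group = max((a.group_index for a in res.atoms), default=-1) + 1
            for n in names:
                res.atoms.append(AtomRecord(n, d.new_type, d.new_charge, group))
                res.bonds.append((n, d.control_atoms[0]))
        elif isinstance(d, ImproperAdd):
            res.impropers.append(d.quad)
    res.total_charge = res.charge_sum()
    return res


def resolve_patched_residues(
    source: ForceFieldSource, patched_residues: list[tuple[str, str, str]]
) -> dict[str, ResidueTopology]:
    """Mint the standalone patched residues requested by the configuration;
    two-residue patches are applied as their side-1 half."""
    out: dict[str, ResidueTopology] = {}
    for base_name, patch_name, new_name in patched_residues:
        base = source.residues[base_name]
        patch = source.patches[patch_name]
        if patch.two_residue:
            patch = split_crosslink_patch(patch, side=1)
        out[new_name] = apply_patch(base, patch, new_name)
    return out
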