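"""Heuristic perception of local internal geometry from bonded connectivity.

The converter has no 3-D coordinates and no internal-coordinate tables to work
with; everything downstream (hydrogen addition rules, termini construction,
collinearity detection) is driven by what can be inferred from the bond graph
plus the numeric parameter tables.

The core device is the *bonded tree*: a breadth-first expansion from a root
atom through declared bonds, pruning any child that already appears among its
own path ancestors (rings are walked around, never through).  Valence angles
are the simple paths of two bonds, proper dihedrals the simple paths of three
bonds; reversed duplicates (A-B-C vs C-B-A) are discarded.

For chainable residues (amino acids, nucleotides, ...) an infinite homopolymer
of the same building block is assumed, so terms crossing the ``+``/``-``
junction are enumerated too.  For terminal caps, closure against every
chainable residue of the same class is attempted and the union of terms kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Optional, Sequence

from .model import (
    FFError,
    ForceFieldSource,
    ParameterTables,
    ResidueTopology,
    is_chain_prefixed,
    strip_chain_prefix,
)
from .units import HYDROGEN_MASS_CUTOFF

Node = Hashable

PLANAR = "planar"
TETRAHEDRAL = "tetrahedral"
LINEAR = "linear"
THREEFOLD = "threefold"

TETRAHEDRAL_ANGLE = 109.5
PLANAR_ANGLE = 120.0


# ---------------------------------------------------------------------------
# generic bond-graph machinery
# ---------------------------------------------------------------------------


def adjacency_from_bonds(
    bonds: Iterable[tuple[Node, Node]]
) -> dict[Node, list[Node]]:
    """Neighbor lists in first-appearance order (deterministic)."""
    adj: dict[Node, list[Node]] = {}
    for a, b in bonds:
        if a == b:
            raise FFError(f"self-bond on {a!r}")
        adj.setdefault(a, [])
        adj.setdefault(b, [])
        if b not in adj[a]:
            adj[a].append(b)
        if a not in adj[b]:
            adj[b].append(a)
    return adj


@dataclass
class BondedTree:
    """Acyclic bond expansion from one root: per-depth (atom, parent) layers
    plus every simple path from the root, up to ``max_depth`` bonds."""

    root: Node
    layers: list[list[tuple[Node, Optional[Node]]]]
    paths: list[tuple[Node, ...]] = field(default_factory=list)

    @property
    def visited(self) -> set[Node]:
        return {atom for layer in self.layers for atom, _parent in layer}


def build_tree(
    adj: dict[Node, list[Node]], root: Node, max_depth: int = 3
) -> BondedTree:
    if root not in adj:
        raise FFError(f"root atom {root!r} has no bonds")
    layers: list[list[tuple[Node, Optional[Node]]]] = [[(root, None)]]
    all_paths: list[tuple[Node, ...]] = [(root,)]
    frontier: list[tuple[Node, ...]] = [(root,)]
    for _depth in range(max_depth):
        nxt: list[tuple[Node, ...]] = []
        layer: list[tuple[Node, Optional[Node]]] = []
        for path in frontier:
            tip = path[-1]
            for child in adj[tip]:
                if child in path:  # ring avoidance: per-path ancestors only
                    continue
                new = path + (child,)
                nxt.append(new)
                if (child, tip) not in layer:
                    layer.append((child, tip))
        if not nxt:
            break
        layers.append(layer)
        all_paths.extend(nxt)
        frontier = nxt
    return BondedTree(root=root, layers=layers, paths=all_paths)


def _canon(path: Sequence[Node]) -> tuple[Node, ...]:
    t = tuple(path)
    r = t[::-1]
    return t if _key(t) <= _key(r) else r


def _key(t: tuple[Node, ...]) -> tuple[str, ...]:
    return tuple(str(x) for x in t)


def enumerate_angles_dihedrals(
    bonds: Iterable[tuple[Node, Node]]
) -> tuple[list[tuple[Node, Node, Node]], list[tuple[Node, Node, Node, Node]]]:
    """All simple paths of 2 and 3 bonds, deduplicated under reversal.

    Works on any bond list (atom names, integers, ...); order of the output is
    a pure function of input order: paths appear by first traversal from the
    earliest root.
    """
    adj = adjacency_from_bonds(bonds)
    angles: dict[tuple[Node, ...], None] = {}
    dihedrals: dict[tuple[Node, ...], None] = {}
    for root in adj:
        tree = build_tree(adj, root, max_depth=3)
        for path in tree.paths:
            if len(path) == 3:
                angles.setdefault(_canon(path))
            elif len(path) == 4:
                dihedrals.setdefault(_canon(path))
    return list(angles), list(dihedrals)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# chain closure
# ---------------------------------------------------------------------------

_SHIFT_SPAN = 2  # copies -2..+2 are enough for any path of <= 3 bonds


def _closure_bonds(
    residue: ResidueTopology, partner: Optional[ResidueTopology]
) -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """Bond list of the (semi-)infinite polymer graph.

    Node = (shift, atom name).  Shift 0 is the residue itself; other shifts
    are copies of ``partner`` (the residue itself for a homopolymer).  Bonds
    to ``+X``/``-X`` connect adjacent copies.
    """
    def block(shift: int) -> Optional[ResidueTopology]:
        if shift == 0:
            return residue
        return partner

    bonds: list[tuple[tuple[int, str], tuple[int, str]]] = []
    for shift in range(-_SHIFT_SPAN, _SHIFT_SPAN + 1):
        blk = block(shift)
        if blk is None:
            continue
        for a, b in blk.bonds:
            end: list[tuple[int, str]] = []
            ok = True
            for x in (a, b):
                if x.startswith("+"):
                    target = block(shift + 1)
                    nm = x[1:]
                    if shift + 1 > _SHIFT_SPAN or target is None or not target.has_atom(nm):
                        ok = False
                        break
                    end.append((shift + 1, nm))
                elif x.startswith("-"):
                    target = block(shift - 1)
                    nm = x[1:]
                    if shift - 1 < -_SHIFT_SPAN or target is None or not target.has_atom(nm):
                        ok = False
                        break
                    end.append((shift - 1, nm))
                else:
                    if not blk.has_atom(x):
                        ok = False
                        break
                    end.append((shift, x))
            if ok:
                bonds.append((end[0], end[1]))
    return bonds


def _express(term: Sequence[tuple[int, str]], homopolymer: bool) -> Optional[tuple[str, ...]]:
    """Map a (shift, name) term onto chain-prefixed atom names.

    For a homopolymer the term may be shifted by any integer; the canonical
    representative maximizes the number of unprefixed atoms, then prefers the
    ``-`` side, which makes the enumeration independent of which side of the
    junction it was walked from.  Terms that cannot be expressed with single
    ``+``/``-`` prefixes are dropped (only possible for degenerate one- or
    two-atom repeat units).
    """
    shifts = [s for s, _n in term]
    candidates = []
    offsets = range(min(shifts), max(shifts) + 1) if homopolymer else (0,)
    for off in offsets:
        moved = [s - off for s in shifts]
        if all(-1 <= s <= 1 for s in moved):
            zeros = sum(1 for s in moved if s == 0)
            candidates.append((-zeros, sum(moved), tuple(moved)))
    if not candidates:
        return None
    _, _, best = min(candidates)
    names = []
    for s, (_s0, name) in zip(best, term):
        names.append({-1: "-", 0: "", 1: "+"}[s] + name)
    return tuple(names)


def term_shift_variants(term: Sequence[str]) -> list[tuple[str, ...]]:
    """All whole-chain-shifted representations of a prefixed name term that
    stay within single +/- prefixes (used to match sub-terms of junction
    terms against independently canonicalized keys)."""
    level = {"-": -1, "+": 1}
    levels = [level.get(n[:1], 0) for n in term]
    bases = [strip_chain_prefix(n) for n in term]
    out = []
    for s in (-1, 0, 1):
        moved = [l + s for l in levels]
        if all(-1 <= m <= 1 for m in moved):
            out.append(
                tuple({-1: "-", 0: "", 1: "+"}[m] + b for m, b in zip(moved, bases))
            )
    return out


def chain_partners(
    residue: ResidueTopology, source: ForceFieldSource
) -> list[Optional[ResidueTopology]]:
    """Closure partners to attempt: itself for a chainable residue; every
    chainable residue of the same class for a terminal cap; none otherwise."""
    if residue.chainable:
        return [residue]
    if residue.prefixed_bonds():
        partners = [
            r
            for r in source.retained_residues().values()
            if r.chainable and r.group == residue.group and r.name != residue.name
        ]
        return partners or [None]
    return [None]


def enumerate_residue_terms(
    residue: ResidueTopology, partner: Optional[ResidueTopology]
) -> tuple[list[tuple[str, ...]], list[tuple[str, ...]]]:
    """Angle triples and dihedral quadruples of one residue, including terms
    crossing the chain junction, expressed with ``+``/``-`` prefixes."""
    bonds = _closure_bonds(residue, partner)
    if not bonds:
        return [], []
    raw_angles, raw_dihedrals = enumerate_angles_dihedrals(bonds)
    homopolymer = partner is residue
    out: dict[int, dict[tuple[str, ...], None]] = {3: {}, 4: {}}
    for terms, n in ((raw_angles, 3), (raw_dihedrals, 4)):
        for term in terms:
            if not any(s == 0 for s, _nm in term):
                continue  # a pure copy of a neighboring residue's term
            expressed = _express(term, homopolymer)
            if expressed is None:
                continue
            out[n].setdefault(_canon(expressed))  # type: ignore[arg-type]
    return list(out[3]), list(out[4])  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# numeric assignment and classification
# ---------------------------------------------------------------------------


@dataclass
class PerceivedGeometry:
    residue: str
    angles: dict[tuple[str, ...], Optional[float]] = field(default_factory=dict)
    dihedrals: dict[tuple[str, ...], list[tuple[int, float]]] = field(
        default_factory=dict
    )
    wildcard_dihedrals: set[tuple[str, ...]] = field(default_factory=set)
    missing_angles: list[tuple[str, ...]] = field(default_factory=list)
    missing_dihedrals: list[tuple[str, ...]] = field(default_factory=list)
    impropers: dict[tuple[str, ...], Optional[float]] = field(default_factory=dict)
    term_types: dict[tuple[str, ...], tuple[str, ...]] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    hydrogens: dict[str, list[str]] = field(default_factory=dict)
    heavy_neighbors: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def dihedral_types_missing(self) -> list[tuple[str, ...]]:
        return list(self.missing_dihedrals)


def _type_resolver(
    residue: ResidueTopology, partner: Optional[ResidueTopology]
) -> Callable[[str], Optional[str]]:
    def resolve(name: str) -> Optional[str]:
        if name.startswith(("+", "-")):
            blk = partner
            name = name[1:]
        else:
            blk = residue
        if blk is None or not blk.has_atom(name):
            return None
        return blk.atom(name).type

    return resolve


def _is_hydrogen(type_name: str, params: ParameterTables) -> bool:
    m = params.masses.get(type_name)
    return m is not None and m.mass < HYDROGEN_MASS_CUTOFF


def perceive_residue(
    residue: ResidueTopology,
    source: ForceFieldSource,
    collinearity_threshold: float = 175.0,
    planarity_tolerance: float = 8.0,
) -> PerceivedGeometry:
    """Full perception pass for one residue: enumerate angle/dihedral terms
    (with chain closure), attach equilibrium values from the parameter
    tables, and classify every hydrogen-bearing heavy atom."""
    geom = PerceivedGeometry(residue=residue.name)
    params = source.params

    partners = chain_partners(residue, source)
    angle_terms: dict[tuple[str, ...], list] = {}
    dihedral_terms: dict[tuple[str, ...], list] = {}
    for partner in partners:
        a_terms, d_terms = enumerate_residue_terms(residue, partner)
        for t in a_terms:
            angle_terms.setdefault(t, []).append(partner)
        for t in d_terms:
            dihedral_terms.setdefault(t, []).append(partner)

    # equilibrium angles; a term crossing the junction may type differently
    # depending on the closure partner -- the first hit wins, others warn
    for term, term_partners in angle_terms.items():
        values: list[float] = []
        for partner in term_partners:
            resolve = _type_resolver(residue, partner)
            types = [resolve(n) for n in term]
            if None in types:
                continue
            geom.term_types.setdefault(term, tuple(types))  # type: ignore[arg-type]
            hit = params.lookup_angle(*types)  # type: ignore[arg-type]
            if hit is not None and hit.theta0 not in values:
                values.append(hit.theta0)
        if len(values) > 1:
            geom.warnings.append(
                f"{residue.name}: conflicting theta0 for {term} across "
                "closure partners; keeping the first"
            )
        if values:
            geom.angles[term] = values[0]
        else:
            geom.angles[term] = None
            geom.missing_angles.append(term)

    # dihedral multiplicities
    for term, term_partners in dihedral_terms.items():
        found = False
        for partner in term_partners:
            resolve = _type_resolver(residue, partner)
            types = [resolve(n) for n in term]
            if None in types:
                continue
            geom.term_types.setdefault(term, tuple(types))  # type: ignore[arg-type]
            hit, wild = params.lookup_dihedral(types)  # type: ignore[arg-type]
            if hit is not None:
                geom.dihedrals[term] = [(t.n, t.delta) for t in hit]
                if wild:
                    geom.wildcard_dihedrals.add(term)
                found = True
                break
        if not found:
            geom.missing_dihedrals.append(term)

    # declared impropers with their minimum positions
    resolve0 = _type_resolver(residue, partners[0])
    for quad in residue.impropers:
        types = [resolve0(n) for n in quad]
        if None in types:
            geom.impropers[quad] = None
            continue
        geom.term_types.setdefault(quad, tuple(types))  # type: ignore[arg-type]
        hit, _wild = params.lookup_improper(types)  # type: ignore[arg-type]
        geom.impropers[quad] = hit.psi0 if hit is not None else None

    # hydrogen bookkeeping and heavy-atom classification
    adj: dict[str, list[str]] = {a.name: [] for a in residue.atoms}
    for a, b in residue.bonds:
        for x, y in ((a, b), (b, a)):
            if not is_chain_prefixed(x):
                adj[x].append(y)
    for atom in residue.atoms:
        if _is_hydrogen(atom.type, params):
            continue
        hs = [
            n
            for n in adj[atom.name]
            if not is_chain_prefixed(n)
            and _is_hydrogen(residue.atom(n).type, params)
        ]
        heavies = [
            n
            for n in adj[atom.name]
            if is_chain_prefixed(n)
            or not _is_hydrogen(residue.atom(n).type, params)
        ]
        geom.heavy_neighbors[atom.name] = heavies
        if hs:
            geom.hydrogens[atom.name] = hs
            geom.classification[atom.name] = classify_center(
                atom.name,
                geom,
                collinearity_threshold=collinearity_threshold,
                planarity_tolerance=planarity_tolerance,
            )
    return geom


def classify_center(
    atom: str,
    geom: PerceivedGeometry,
    collinearity_threshold: float = 175.0,
    planarity_tolerance: float = 8.0,
) -> str:
    """Classify a heavy atom's coordination from perceived terms.

    Decision cascade (first hit wins):

    1. an improper dihedral centered on the atom with a 0 or 180 degree
       minimum -> planar;
    2. any incident valence angle with theta0 at or above the collinearity
       threshold -> linear;
    3. dominant proper-dihedral multiplicity about the atom's bonds: n=3 ->
       threefold (tetrahedral); n=2 with delta=180 -> planar;
    4. mean incident theta0 within the tolerance of 109.5 -> tetrahedral, of
       120 -> planar;
    5. otherwise tetrahedral, with a warning.
    """
    for quad, psi0 in geom.impropers.items():
        if strip_chain_prefix(quad[0]) == atom and psi0 is not None:
            if min(abs(psi0), abs(abs(psi0) - 180.0)) < 1e-6:
                return PLANAR

    incident = [
        (term, th)
        for term, th in geom.angles.items()
        if th is not None and strip_chain_prefix(term[1]) == atom
    ]
    if any(th >= collinearity_threshold for _t, th in incident):
        return LINEAR

    mult_votes: dict[tuple[int, float], int] = {}
    for term, nds in geom.dihedrals.items():
        if atom in (strip_chain_prefix(term[1]), strip_chain_prefix(term[2])):
            for n, delta in nds:
                key = (n, delta)
                mult_votes[key] = mult_votes.get(key, 0) + 1
    if mult_votes:
        (n, delta), _count = max(
            mult_votes.items(), key=lambda kv: (kv[1], -kv[0][0])
        )
        if n == 3:
            return THREEFOLD
        if n == 2 and abs(delta - 180.0) < 1e-6:
            return PLANAR

    if incident:
        mean = sum(th for _t, th in incident) / len(incident)
        if abs(mean - TETRAHEDRAL_ANGLE) <= planarity_tolerance:
            return TETRAHEDRAL
        if abs(mean - PLANAR_ANGLE) <= planarity_tolerance:
            return PLANAR

    geom.warnings.append(
        f"{geom.residue}: center {atom} unclassifiable; defaulting to tetrahedral"
    )
    return TETRAHEDRAL
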