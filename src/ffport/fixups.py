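"""Post-conversion repairs for two engine-difference failure modes.

1. *Collinear dihedrals.*  Whenever one of a proper dihedral's internal
   valence angles has its minimum at (or near) 180 degrees, the torsion angle
   is geometrically undefined and the source force field simply never defines
   a parameter for it (the source engine skips such terms by inspecting its
   internal-coordinate tables).  The downstream topology builder enumerates
   every dihedral regardless and would refuse to run on the "missing"
   parameter.  The repair is a dummy dihedral type with zero force constant:
   no forces, no error.

2. *Improper permutations.*  The source engine accepts the three non-central
   atoms of an improper in any order; the downstream engine matches the
   declared order (or its reverse) only.  When a residue declares an improper
   whose types only match a parameter under a permutation, the parameter is
   replicated under the declared order.

Both repairs are written to a separate include file (ffmissingdihedrals.itp)
rather than the main bonded file, keeping provenance obvious.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .geometry import PerceivedGeometry, _canon, term_shift_variants
from .model import (
    FFError,
    ImproperParam,
    ParameterTables,
    ResidueTopology,
    canonical_quad,
    canonical_triplet,
)


@dataclass
class DummyDihedral:
    types: tuple[str, str, str, str]
    kchi: float = 0.0
    n: int = 1
    delta: float = 0.0


@dataclass
class PermutedImproper:
    residue: str
    declared_types: tuple[str, str, str, str]
    matched_key: tuple[str, str, str, str]
    param: ImproperParam
    all_matches: list[tuple[str, str, str, str]] = field(default_factory=list)


@dataclass
class MissingTermReport:
    dummy_dihedraltypes: list[DummyDihedral] = field(default_factory=list)
    permuted_impropertypes: list[PermutedImproper] = field(default_factory=list)


def _internal_angle_theta0(
    term: tuple[str, ...], geom: PerceivedGeometry
) -> list[float]:
    """theta0 values of the two valence angles inside a dihedral term."""
    out = []
    for sub in (term[0:3], term[1:4]):
        for variant in term_shift_variants(sub):
            th = geom.angles.get(_canon(variant))
            if th is not None:
                out.append(th)
                break
    return out


def find_missing_dihedrals(
    residues: dict[str, ResidueTopology],
    geometries: dict[str, PerceivedGeometry],
    params: ParameterTables,
    collinearity_threshold: float = 175.0,
) -> list[DummyDihedral]:
    """Zero-force dummy types for every unparameterized dihedral whose
    geometry is collinear; a genuinely missing (non-collinear) parameter is a
    hard error naming the residue and types."""
    dummies: dict[tuple[str, str, str, str], DummyDihedral] = {}
    genuine: list[str] = []
    for name, geom in geometries.items():
        if name not in residues:
            continue
        for term in geom.missing_dihedrals:
            types = geom.term_types.get(term)
            if types is None:
                genuine.append(f"{name}: {term} (atom types unresolvable)")
                continue
            thetas = _internal_angle_theta0(term, geom)
            if any(th >= collinearity_threshold for th in thetas):
                key = canonical_quad(types)
                dummies.setdefault(key, DummyDihedral(types=key))
            else:
                genuine.append(f"{name}: {term} types {types}")
    if genuine:
        raise FFError(
            "missing dihedral parameters (not collinear, cannot be dummied):\n  "
            + "\n  ".join(genuine)
        )
    return list(dummies.values())


def resolve_improper_permutations(
    residues: dict[str, ResidueTopology],
    geometries: dict[str, PerceivedGeometry],
    params: ParameterTables,
) -> list[PermutedImproper]:
    """Replicated improper parameters for residue impropers that only match
    the table under a permutation of the three non-central atoms (the central
    atom stays first)."""
    out: dict[tuple[str, str, str, str], PermutedImproper] = {}
    for name, geom in geometries.items():
        if name not in residues:
            continue
        for quad, psi0 in geom.impropers.items():
            if psi0 is not None:
                continue  # matched as declared (exact or wildcard)
            types = geom.term_types.get(quad)
            if types is None:
                continue  # chain-prefixed atoms unresolvable; not our case
            hits: list[tuple[tuple[str, str, str, str], ImproperParam]] = []
            seen: set[tuple[str, str, str, str]] = set()
            for perm in itertools.permutations(types[1:4]):
                candidate = (types[0],) + perm
                hit, _wild = params.lookup_improper(candidate)
                if hit is None:
                    continue
                key = canonical_quad(candidate)
                if key in seen:
                    continue
                seen.add(key)
                hits.append((key, hit))
            if not hits:
                raise FFError(
                    f"residue {name}: improper {quad} (types {types}) has no "
                    "parameter under any permutation"
                )
            matched_key, param = hits[0]
            declared = canonical_quad(types)
            if declared not in out:
                out[declared] = PermutedImproper(
                    residue=name,
                    declared_types=declared,
                    matched_key=matched_key,
                    param=ImproperParam(param.kpsi, param.psi0),
                    all_matches=[k for k, _p in hits],
                )
    return list(out.values())


def run_fixups(
    residues: dict[str, ResidueTopology],
    geometries: dict[str, PerceivedGeometry],
    params: ParameterTables,
    collinearity_threshold: float = 175.0,
) -> MissingTermReport:
    return MissingTermReport(
        dummy_dihedraltypes=find_missing_dihedrals(
            residues, geometries, params, collinearity_threshold
        ),
        permuted_impropertypes=resolve_improper_permutations(
            residues, geometries, params
        ),
    )


def check_completeness(
    residues: dict[str, ResidueTopology],
    geometries: dict[str, PerceivedGeometry],
    params: ParameterTables,
    report: MissingTermReport,
) -> list[str]:
    """After fixups, every enumerated bonded term of every retained residue
    must have a parameter; returns the list of violations (empty = pass)."""
    problems: list[str] = []
    dummy_keys = {d.types for d in report.dummy_dihedraltypes}
    replicated = {p.declared_types for p in report.permuted_impropertypes}
    for name, geom in geometries.items():
        if name not in residues:
            continue
        for term in geom.missing_angles:
            problems.append(f"{name}: angle {term} unparameterized")
        for term in geom.missing_dihedrals:
            types = geom.term_types.get(term)
            if types is None or canonical_quad(types) not in dummy_keys:
                problems.append(f"{name}: dihedral {term} unparameterized")
        for quad, psi0 in geom.impropers.items():
            if psi0 is not None:
                continue
            types = geom.term_types.get(quad)
            if types is None or canonical_quad(types) not in replicated:
                problems.append(f"{name}: improper {quad} unparameterized")
        res = residues[name]
        for (a, b) in res.internal_bonds():
            ta, tb = res.atom(a).type, res.atom(b).type
            if params.lookup_bond(ta, tb) is None:
                problems.append(f"{name}: bond {a}-{b} ({ta},{tb}) unparameterized")
    return problems
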