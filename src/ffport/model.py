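"""In-memory model of a CHARMM-format force field.

Everything parsed from rtf/prm/str files lands in these containers.  Order is
preserved everywhere (dicts keep insertion order), identifiers keep their
original case, and every record carries ``file:line`` provenance so errors can
point back at the source text.

Conventions kept from the source format:

* chain-prefixed atom names (``+N``, ``-C``) stay literal strings; they are
  resolved only by the geometry-perception stage;
* Lennard-Jones epsilons are stored as parsed (CHARMM prints them negative);
* the wildcard atom type is the literal ``X``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

WILDCARD = "X"

CHAIN_PREFIXES = ("+", "-")


class FFError(Exception):
    """Hard error in parsing, merging, conversion or writing."""


def strip_chain_prefix(name: str) -> str:
    return name[1:] if name and name[0] in CHAIN_PREFIXES else name


def is_chain_prefixed(name: str) -> bool:
    return bool(name) and name[0] in CHAIN_PREFIXES


@dataclass
class AtomRecord:
    """One ATOM line of a RESI/PRES block."""

    name: str
    type: str
    charge: float
    group_index: int = 0

    def copy(self) -> "AtomRecord":
        return dataclasses.replace(self)


@dataclass
class ResidueTopology:
    name: str
    total_charge: float
    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    impropers: list[tuple[str, str, str, str]] = field(default_factory=list)
    cmaps: list[tuple[str, ...]] = field(default_factory=list)
    group: str = ""
    chainable: bool = False
    has_lone_pairs: bool = False
    source: str = ""
    annotations: list[str] = field(default_factory=list)

    # -- lookups ----------------------------------------------------------
    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def charge_sum(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def group_charges(self) -> dict[int, float]:
        sums: dict[int, float] = {}
        for a in self.atoms:
            sums[a.group_index] = sums.get(a.group_index, 0.0) + a.charge
        return sums

    def copy(self, name: Optional[str] = None) -> "ResidueTopology":
        return ResidueTopology(
            name=name if name is not None else self.name,
            total_charge=self.total_charge,
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            impropers=list(self.impropers),
            cmaps=list(self.cmaps),
            group=self.group,
            chainable=self.chainable,
            has_lone_pairs=self.has_lone_pairs,
            source=self.source,
            annotations=list(self.annotations),
        )

    def internal_bonds(self) -> list[tuple[str, str]]:
        """Bonds between two unprefixed atoms of this residue."""
        return [
            (a, b)
            for a, b in self.bonds
            if not is_chain_prefixed(a) and not is_chain_prefixed(b)
        ]

    def prefixed_bonds(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in self.bonds
            if is_chain_prefixed(a) or is_chain_prefixed(b)
        ]


@dataclass
class PatchTopology:
    """A PRES block: atom additions/replacements plus explicit deletions."""

    name: str
    total_charge: float
    deleted_atoms: list[str] = field(default_factory=list)
    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    impropers: list[tuple[str, str, str, str]] = field(default_factory=list)
    deleted_impropers: list[tuple[str, str, str, str]] = field(default_factory=list)
    cmaps: list[tuple[str, ...]] = field(default_factory=list)
    two_residue: bool = False
    source: str = ""
    annotations: list[str] = field(default_factory=list)

    def validate(self) -> None:
        added = {a.name for a in self.atoms}
        overlap = added & set(self.deleted_atoms)
        if overlap:
            raise FFError(
                f"patch {self.name}: atoms both added and deleted: {sorted(overlap)}"
            )


# ---------------------------------------------------------------------------
# numeric parameter tables
# ---------------------------------------------------------------------------


@dataclass
class BondParam:
    kb: float  # kcal mol^-1 A^-2 (CHARMM prints K; V = K (b-b0)^2)
    b0: float  # Angstrom


@dataclass
class AngleParam:
    ktheta: float  # kcal mol^-1 rad^-2
    theta0: float  # degrees
    kub: Optional[float] = None  # kcal mol^-1 A^-2
    s0: Optional[float] = None  # Angstrom


@dataclass
class DihedralParam:
    kchi: float  # kcal mol^-1
    n: int
    delta: float  # degrees


@dataclass
class ImproperParam:
    kpsi: float  # kcal mol^-1 rad^-2
    psi0: float  # degrees


@dataclass
class LJParam:
    epsilon: float  # kcal mol^-1, as printed (negative)
    rmin2: float  # R_min/2, Angstrom
    epsilon14: Optional[float] = None
    rmin2_14: Optional[float] = None


@dataclass
class NBFixParam:
    epsilon: float  # kcal mol^-1, as printed (negative)
    rmin: float  # full R_min, Angstrom


@dataclass(eq=False)
class CmapGrid:
    resolution: int  # number of grid points per dimension
    grid: np.ndarray  # (resolution, resolution), kcal mol^-1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CmapGrid):
            return NotImplemented
        return self.resolution == other.resolution and np.array_equal(
            self.grid, other.grid
        )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.resolution, self.resolution):
            raise FFError(
                f"CMAP grid shape {self.grid.shape} does not match "
                f"resolution {self.resolution}"
            )
        if 360 % self.resolution:
            raise FFError(f"CMAP resolution {self.resolution} does not divide 360")


@dataclass
class MassEntry:
    mass: float  # amu
    element: str


def canonical_pair(key: Sequence[str]) -> tuple[str, str]:
    a, b = key
    return (a, b) if (a, b) <= (b, a) else (b, a)


def canonical_triplet(key: Sequence[str]) -> tuple[str, str, str]:
    t = tuple(key)
    r = t[::-1]
    return t if t <= r else r  # type: ignore[return-value]


def canonical_quad(key: Sequence[str]) -> tuple[str, str, str, str]:
    t = tuple(key)
    r = t[::-1]
    return t if t <= r else r  # type: ignore[return-value]


@dataclass
class ParameterTables:
    """All numeric parameters of the source files, in CHARMM units.

    Keys are canonicalized under reversal at insertion; lookup helpers apply
    the exact-before-wildcard precedence rule.
    """

    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], list[DihedralParam]] = field(
        default_factory=dict
    )
    impropers: dict[tuple[str, str, str, str], ImproperParam] = field(
        default_factory=dict
    )
    lj: dict[str, LJParam] = field(default_factory=dict)
    nbfix: dict[tuple[str, str], NBFixParam] = field(default_factory=dict)
    cmaps: dict[tuple[str, ...], CmapGrid] = field(default_factory=dict)
    masses: dict[str, MassEntry] = field(default_factory=dict)

    # -- lookup helpers ---------------------------------------------------
    def lookup_bond(self, t1: str, t2: str) -> Optional[BondParam]:
        return self.bonds.get(canonical_pair((t1, t2)))

    def lookup_angle(self, t1: str, t2: str, t3: str) -> Optional[AngleParam]:
        return self.angles.get(canonical_triplet((t1, t2, t3)))

    def lookup_dihedral(
        self, types: Sequence[str]
    ) -> tuple[Optional[list[DihedralParam]], bool]:
        """Return (parameter list, wildcard_matched); exact match first."""
        key = canonical_quad(types)
        hit = self.dihedrals.get(key)
        if hit is not None:
            return hit, False
        wkey = canonical_quad((WILDCARD, types[1], types[2], WILDCARD))
        hit = self.dihedrals.get(wkey)
        if hit is not None:
            return hit, True
        return None, False

    def lookup_improper(
        self, types: Sequence[str]
    ) -> tuple[Optional[ImproperParam], bool]:
        key = canonical_quad(types)
        hit = self.impropers.get(key)
        if hit is not None:
            return hit, False
        wkey = canonical_quad((types[0], WILDCARD, WILDCARD, types[3]))
        hit = self.impropers.get(wkey)
        if hit is not None:
            return hit, True
        return None, False

    def lookup_nbfix(self, t1: str, t2: str) -> Optional[NBFixParam]:
        return self.nbfix.get(canonical_pair((t1, t2)))

    # -- counting ---------------------------------------------------------
    def counts(self) -> dict[str, int]:
        return {
            "bonds": len(self.bonds),
            "angles": len(self.angles),
            "dihedrals": sum(len(v) for v in self.dihedrals.values()),
            "impropers": len(self.impropers),
            "lj": len(self.lj),
            "nbfix": len(self.nbfix),
            "cmaps": len(self.cmaps),
            "masses": len(self.masses),
        }


# ---------------------------------------------------------------------------
# whole-source container and conversion configuration
# ---------------------------------------------------------------------------


@dataclass
class ForceFieldSource:
    """Parsed, order-preserving model of one or more CHARMM input files."""

    residues: dict[str, ResidueTopology] = field(default_factory=dict)
    patches: dict[str, PatchTopology] = field(default_factory=dict)
    params: ParameterTables = field(default_factory=ParameterTables)
    files: list[str] = field(default_factory=list)
    discarded: list[str] = field(default_factory=list)  # DONOR/ACCEPTOR/IC notes
    warnings: list[str] = field(default_factory=list)

    def retained_residues(self) -> dict[str, ResidueTopology]:
        """Residues that survive conversion (lone-pair residues excluded)."""
        return {n: r for n, r in self.residues.items() if not r.has_lone_pairs}


@dataclass
class ConversionConfig:
    """Parsed conversion-control file (the single reproducibility input)."""

    input_files: list[tuple[str, str, str]] = field(default_factory=list)
    #: (path, dialect rtf|prm|str, residue-class label)
    ff_name: str = "ffport"
    description: str = "Force field ported from CHARMM format"
    patched_residues: list[tuple[str, str, str]] = field(default_factory=list)
    #: (base_residue, patch_name, new_residue_name)
    termini_patches: list[tuple[str, str]] = field(default_factory=list)
    #: (patch_name, side "N"|"C")
    copyresidues: list[tuple[str, str]] = field(default_factory=list)
    extra_terminal_deletes: list[str] = field(default_factory=list)
    citation_db: Optional[str] = None
    citations: list[tuple[str, str]] = field(default_factory=list)  # (residue, key)
    residue_conflicts: dict[str, str] = field(default_factory=dict)
    water_models: list[str] = field(default_factory=lambda: ["tip3p_charmm"])
    pairtypes_mode: str = "overrides"  # or "full"
    collinearity_threshold: float = 175.0  # degrees
    planarity_tolerance: float = 8.0  # degrees, classify_center band

    def validate_against(self, source: ForceFieldSource) -> None:
        names = set(source.residues)
        patches = set(source.patches)
        for base, patch, new in self.patched_residues:
            if base not in names:
                raise FFError(f"patched residue: unknown base residue {base!r}")
            if patch not in patches:
                raise FFError(f"patched residue: unknown patch {patch!r}")
            if new in names:
                raise FFError(f"patched residue target {new!r} collides with an existing residue")
        for patch, _side in self.termini_patches:
            if patch not in patches:
                raise FFError(f"terminus patch {patch!r} not found")
        for src, alias in self.copyresidues:
            if src not in names:
                raise FFError(f"copyresidues: unknown source residue {src!r}")
            if alias in names:
                raise FFError(f"copyresidues alias {alias!r} collides with an existing residue")


def validate_merged(source: ForceFieldSource, charge_tol: float = 1e-4) -> list[str]:
    """Cross-checks after merging; returns warnings, raises FFError on
    missing mass/LJ coverage."""
    warnings: list[str] = []
    for res in source.retained_residues().values():
        missing = [
            a.type
            for a in res.atoms
            if a.type not in source.params.masses or a.type not in source.params.lj
        ]
        if missing:
            raise FFError(
                f"residue {res.name}: atom types without mass/LJ entries: "
                f"{sorted(set(missing))}"
            )
        if abs(res.charge_sum() - res.total_charge) > charge_tol:
            warnings.append(
                f"residue {res.name}: charge sum {res.charge_sum():.6f} differs "
                f"from declared {res.total_charge:.6f}"
            )
        for gi, q in res.group_charges().items():
            if abs(q - round(q)) > 1e-6:
                warnings.append(
                    f"residue {res.name}: charge group {gi} sum {q:.6f} not integral"
                )
        known = set(res.atom_names)
        for a, b in res.bonds:
            for x in (a, b):
                if not is_chain_prefixed(x) and x not in known:
                    raise FFError(f"residue {res.name}: bond references unknown atom {x!r}")
        for quad in res.impropers:
            for x in quad:
                if not is_chain_prefixed(x) and x not in known:
                    raise FFError(f"residue {res.name}: improper references unknown atom {x!r}")
        for octet in res.cmaps:
            for x in octet:
                if not is_chain_prefixed(x) and x not in known:
                    raise FFError(f"residue {res.name}: CMAP references unknown atom {x!r}")
    return warnings
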