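"""Synthetic toy force fields in CHARMM format.

Every stage of the converter is testable without downloading a force-field
release: this module emits a small (2-10 residue) but structurally complete
file set — residue topology, parameter and stream files plus a matching
conversion-control file and a BibTeX database — exercising every parsed
construct: RESI, single- and two-residue PRES, MASS, GROUP, DOUBLE/TRIPLE
bond orders, IMPR, CMAP, DONOR/ACCEPTOR/IC records (to be discarded), NBFIX,
dedicated 1-4 Lennard-Jones parameters, wildcard dihedrals, a
collinear-angle residue, a permuted-improper residue and a lone-pair
residue.

The chemistry is deliberately cartoonish but self-consistent: an alanine-like
and a cysteine-like chainable amino acid, a capped glycine dipeptide (whose
backbone correction map lies entirely inside the residue), ethanol, 2-butyne
(the collinear case), a planar amidine fragment declaring its improper in a
permuted order, a halogenated carbon with a massless sigma-hole site, a
sodium ion, and filler alkanes.  Numeric parameter values are drawn from a
seeded generator within ranges typical of additive biomolecular force
fields; equilibrium geometry is fixed by chemistry (sp: 180 degrees, sp2:
~120, sp3: ~109.5) so that the perception heuristics face realistic input.

Parameter coverage is guaranteed by construction: the generator runs the
same term enumeration the converter uses and emits one entry per needed type
key — except the deliberately omitted dihedral across the triple bond, which
downstream stages must repair with a zero-force dummy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .charmm_io import _residue_is_chainable
from .geometry import _closure_bonds, chain_partners, enumerate_residue_terms, _type_resolver
from .model import (
    AtomRecord,
    AngleParam,
    BondParam,
    CmapGrid,
    DihedralParam,
    ForceFieldSource,
    ImproperParam,
    LJParam,
    MassEntry,
    NBFixParam,
    ParameterTables,
    PatchTopology,
    ResidueTopology,
    WILDCARD,
    canonical_pair,
    canonical_quad,
    canonical_triplet,
)

CMAP_RESOLUTION = 8  # 45-degree grid; small but structurally faithful

_MASSES = {
    "H": (1.008, "H"), "HC": (1.008, "H"), "HO": (1.008, "H"),
    "HS": (1.008, "H"), "HG": (1.008, "H"),
    "CT": (12.011, "C"), "C": (12.011, "C"), "CY": (12.011, "C"),
    "CG": (12.011, "C"), "CC": (12.011, "C"),
    "N": (14.007, "N"), "NG": (14.007, "N"), "NH3T": (14.007, "N"),
    "O": (15.999, "O"), "OH1": (15.999, "O"), "OE": (15.999, "O"),
    "OC": (15.999, "O"),
    "S": (32.06, "S"), "SM": (32.06, "S"),
    "SOD": (22.98977, "NA"), "CLL": (35.45, "CL"), "LPT": (0.0, "LP"),
}

_PLANAR_CENTERS = {"C", "CC", "CG", "NG", "N"}
_LINEAR_CENTERS = {"CY"}

#: base R_min/2 (A) and epsilon magnitude (kcal/mol) per type
_LJ_BASE = {
    "H": (0.225, 0.046), "HC": (1.34, 0.024), "HO": (0.40, 0.046),
    "HS": (0.45, 0.10), "HG": (1.25, 0.03),
    "CT": (2.06, 0.08), "C": (2.00, 0.11), "CY": (1.99, 0.10),
    "CG": (1.99, 0.07), "CC": (2.00, 0.07),
    "N": (1.85, 0.20), "NG": (1.85, 0.20), "NH3T": (1.85, 0.20),
    "O": (1.70, 0.12), "OH1": (1.77, 0.15), "OE": (1.77, 0.10),
    "OC": (1.70, 0.12),
    "S": (2.00, 0.45), "SM": (1.98, 0.38),
    "SOD": (1.36, 0.047), "CLL": (1.91, 0.30), "LPT": (1.00, 0.01),
}


def _atoms(spec: list[tuple[str, str, float, int]]) -> list[AtomRecord]:
    return [AtomRecord(n, t, q, g) for n, t, q, g in spec]


def _backbone(extra_cb: list[tuple[str, str, float, int]],
              cb_bonds: list[tuple[str, str]], name: str) -> ResidueTopology:
    """Amino-acid-like chainable residue with the shared backbone layout."""
    res = ResidueTopology(name=name, total_charge=0.0)
    res.atoms = _atoms(
        [("N", "N", -0.47, 0), ("HN", "H", 0.31, 0),
         ("CA", "CT", 0.07, 0), ("HA", "HC", 0.09, 0)]
        + extra_cb
        + [("C", "C", 0.51, 9), ("O", "O", -0.51, 9)]
    )
    res.bonds = (
        [("-C", "N"), ("N", "HN"), ("N", "CA"), ("CA", "HA")]
        + cb_bonds
        + [("CA", "C"), ("O", "C")]
    )
    res.impropers = [("N", "-C", "CA", "HN"), ("C", "CA", "+N", "O")]
    res.cmaps = [("-C", "N", "CA", "C", "N", "CA", "C", "+N")]
    return res


def _make_residues() -> list[ResidueTopology]:
    out: list[ResidueTopology] = []

    alx = _backbone(
        [("CB", "CT", -0.27, 1), ("HB1", "HC", 0.09, 1),
         ("HB2", "HC", 0.09, 1), ("HB3", "HC", 0.09, 1)],
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")],
        "ALX",
    )
    out.append(alx)

    cyx = _backbone(
        [("CB", "CT", -0.11, 1), ("HB1", "HC", 0.09, 1),
         ("HB2", "HC", 0.09, 1), ("SG", "S", -0.23, 1), ("HG1", "HS", 0.16, 1)],
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "SG"), ("SG", "HG1")],
        "CYX",
    )
    out.append(cyx)

    glyd = ResidueTopology(name="GLYD", total_charge=0.0)
    glyd.atoms = _atoms([
        ("CAY", "CT", -0.27, 0), ("HY1", "HC", 0.09, 0),
        ("HY2", "HC", 0.09, 0), ("HY3", "HC", 0.09, 0),
        ("CY", "C", 0.51, 1), ("OY", "O", -0.51, 1),
        ("N", "N", -0.47, 2), ("HN", "H", 0.31, 2),
        ("CA", "CT", 0.07, 2), ("HA", "HC", 0.09, 2),
        ("C", "C", 0.51, 3), ("O", "O", -0.51, 3),
        ("NT", "N", -0.47, 4), ("HNT", "H", 0.31, 4),
        ("CAT", "CT", -0.11, 4),
        ("HT1", "HC", 0.09, 4), ("HT2", "HC", 0.09, 4), ("HT3", "HC", 0.09, 4),
    ])
    glyd.bonds = [
        ("CAY", "HY1"), ("CAY", "HY2"), ("CAY", "HY3"), ("CAY", "CY"),
        ("OY", "CY"), ("CY", "N"), ("N", "HN"), ("N", "CA"), ("CA", "HA"),
        ("CA", "C"), ("O", "C"), ("C", "NT"), ("NT", "HNT"), ("NT", "CAT"),
        ("CAT", "HT1"), ("CAT", "HT2"), ("CAT", "HT3"),
    ]
    glyd.impropers = [
        ("CY", "CAY", "N", "OY"), ("C", "CA", "NT", "O"),
        ("N", "CY", "CA", "HN"), ("NT", "C", "CAT", "HNT"),
    ]
    glyd.cmaps = [("CY", "N", "CA", "C", "N", "CA", "C", "NT")]
    out.append(glyd)

    etx = ResidueTopology(name="ETX", total_charge=0.0)
    etx.atoms = _atoms([
        ("C1", "CT", -0.27, 0), ("HA1", "HC", 0.09, 0),
        ("HA2", "HC", 0.09, 0), ("HA3", "HC", 0.09, 0),
        ("C2", "CT", 0.05, 1), ("HB1", "HC", 0.09, 1), ("HB2", "HC", 0.09, 1),
        ("O1", "OH1", -0.65, 1), ("HO1", "HO", 0.42, 1),
    ])
    etx.bonds = [
        ("C1", "HA1"), ("C1", "HA2"), ("C1", "HA3"), ("C1", "C2"),
        ("C2", "HB1"), ("C2", "HB2"), ("C2", "O1"), ("O1", "HO1"),
    ]
    out.append(etx)

    bty = ResidueTopology(name="BTY", total_charge=0.0)
    bty.atoms = _atoms([
        ("C1", "CT", -0.27, 0), ("HA1", "HC", 0.09, 0),
        ("HA2", "HC", 0.09, 0), ("HA3", "HC", 0.09, 0),
        ("C2", "CY", 0.0, 1), ("C3", "CY", 0.0, 2),
        ("C4", "CT", -0.27, 3), ("HB1", "HC", 0.09, 3),
        ("HB2", "HC", 0.09, 3), ("HB3", "HC", 0.09, 3),
    ])
    bty.bonds = [
        ("C1", "HA1"), ("C1", "HA2"), ("C1", "HA3"), ("C1", "C2"),
        ("C2", "C3"),  # rendered as TRIPLE
        ("C3", "C4"), ("C4", "HB1"), ("C4", "HB2"), ("C4", "HB3"),
    ]
    out.append(bty)

    imx = ResidueTopology(name="IMX", total_charge=0.0)
    imx.atoms = _atoms([
        ("N1", "NG", -0.60, 0), ("C1", "CG", 0.20, 0),
        ("C2", "CG", 0.20, 0), ("H1", "HG", 0.20, 0),
    ])
    imx.bonds = [("N1", "C1"), ("N1", "C2"), ("N1", "H1")]
    imx.impropers = [("N1", "C1", "C2", "H1")]  # declared in a permuted order
    out.append(imx)

    lpx = ResidueTopology(name="LPX", total_charge=0.0, has_lone_pairs=True)
    lpx.atoms = _atoms([
        ("C1", "CG", -0.115, 0), ("H1", "HG", 0.115, 0),
        ("CL1", "CLL", -0.18, 1), ("LP1", "LPT", 0.18, 1),
    ])
    lpx.bonds = [("C1", "H1"), ("C1", "CL1")]
    out.append(lpx)

    sod = ResidueTopology(name="SOD", total_charge=1.0)
    sod.atoms = _atoms([("SOD", "SOD", 1.0, 0)])
    out.append(sod)

    for i, length in enumerate((2, 3), start=1):
        mol = ResidueTopology(name=f"MOL{i}", total_charge=0.0)
        stems = ["HA", "HB", "HC"]
        for ci in range(1, length + 1):
            n_h = 3 if ci in (1, length) else 2
            q_c = -0.27 if n_h == 3 else -0.18
            mol.atoms.append(AtomRecord(f"C{ci}", "CT", q_c, ci - 1))
            for hi in range(1, n_h + 1):
                mol.atoms.append(
                    AtomRecord(f"{stems[ci-1]}{hi}", "HC", 0.09, ci - 1)
                )
                mol.bonds.append((f"C{ci}", f"{stems[ci-1]}{hi}"))
            if ci > 1:
                mol.bonds.append((f"C{ci-1}", f"C{ci}"))
        out.append(mol)
    return out


def _make_patches() -> list[PatchTopology]:
    nte = PatchTopology(name="NTE", total_charge=1.0)
    nte.atoms = _atoms([
        ("N", "NH3T", -0.30, 0),
        ("HT1", "HC", 0.33, 0), ("HT2", "HC", 0.33, 0), ("HT3", "HC", 0.33, 0),
        ("CA", "CT", 0.21, 0), ("HA", "HC", 0.10, 0),
    ])
    nte.deleted_atoms = ["HN"]
    nte.bonds = [("HT1", "N"), ("HT2", "N"), ("HT3", "N")]

    cte = PatchTopology(name="CTE", total_charge=-1.0)
    cte.atoms = _atoms([
        ("C", "CC", 0.34, 0), ("OT1", "OC", -0.67, 0), ("OT2", "OC", -0.67, 0),
    ])
    cte.deleted_atoms = ["O"]
    cte.bonds = [("C", "OT1"), ("C", "OT2")]
    cte.impropers = [("C", "CA", "OT2", "OT1")]

    dsx = PatchTopology(name="DSX", total_charge=0.0, two_residue=True)
    dsx.atoms = _atoms([("1SG", "SM", -0.07, 0), ("2SG", "SM", -0.07, 0)])
    dsx.deleted_atoms = ["1HG1", "2HG1"]
    dsx.bonds = [("1SG", "2SG")]

    ome = PatchTopology(name="OME", total_charge=0.0)
    ome.atoms = _atoms([
        ("O1", "OE", -0.23, 0),
        ("CM1", "CT", -0.27, 0),
        ("HM1", "HC", 0.09, 0), ("HM2", "HC", 0.09, 0), ("HM3", "HC", 0.09, 0),
    ])
    ome.deleted_atoms = ["HO1"]
    ome.bonds = [("O1", "CM1"), ("CM1", "HM1"), ("CM1", "HM2"), ("CM1", "HM3")]
    return [nte, cte, dsx, ome]


# ---------------------------------------------------------------------------
# parameter synthesis
# ---------------------------------------------------------------------------

_BOND_LENGTHS = {
    frozenset(("C", "H")): 1.09, frozenset(("N", "H")): 1.01,
    frozenset(("O", "H")): 0.96, frozenset(("S", "H")): 1.34,
    frozenset(("C", "C")): 1.53, frozenset(("C", "N")): 1.38,
    frozenset(("C", "O")): 1.40, frozenset(("C", "S")): 1.81,
    frozenset(("S", "S")): 2.03, frozenset(("C", "CL")): 1.74,
}

#: central bond pairs covered by a wildcard dihedral instead of exact entries
_WILDCARD_CENTRALS = {
    frozenset(("CT", "OH1")),
    frozenset(("CT", "CY")),
}
#: the deliberate hole: no parameter across the triple bond
_OMITTED_CENTRALS = {frozenset(("CY", "CY"))}


def _element(t: str) -> str:
    return _MASSES[t][1]


def _bond_b0(ta: str, tb: str, rng: np.random.Generator) -> float:
    key = frozenset((_element(ta), _element(tb)))
    base = _BOND_LENGTHS.get(key, 1.50)
    if {ta, tb} == {"CY"}:
        base = 1.21  # triple bond
    elif key == frozenset(("C", "O")) and {ta, tb} <= {"C", "CC", "O", "OC"}:
        base = 1.23  # carbonyl / carboxylate C=O
    return base + rng.uniform(-0.02, 0.02)


class _ParamFactory:
    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.tables = ParameterTables()
        for t, (mass, element) in _MASSES.items():
            self.tables.masses[t] = MassEntry(mass, element)
        for t, (rmin2, eps) in _LJ_BASE.items():
            eps = eps * (1.0 + rng.uniform(-0.1, 0.1))
            lj = LJParam(-round(eps, 4), round(rmin2, 4))
            if t == "CT":  # dedicated 1-4 set, as for sp3 carbons upstream
                lj.epsilon14 = -round(eps * 0.5, 4)
                lj.rmin2_14 = 1.9
            self.tables.lj[t] = lj
        self.tables.nbfix[canonical_pair(("SOD", "OH1"))] = NBFixParam(
            -0.075, 3.19
        )
        self.tables.nbfix[canonical_pair(("SOD", "OC"))] = NBFixParam(
            -0.07, 3.17
        )

    def need_bond(self, ta: str, tb: str) -> None:
        key = canonical_pair((ta, tb))
        if key in self.tables.bonds:
            return
        heavy = _element(ta) != "H" and _element(tb) != "H"
        k = self.rng.uniform(180, 350) if heavy else self.rng.uniform(320, 420)
        self.tables.bonds[key] = BondParam(
            round(k, 2), round(_bond_b0(ta, tb, self.rng), 4)
        )

    def need_angle(self, ta: str, tb: str, tc: str) -> None:
        key = canonical_triplet((ta, tb, tc))
        if key in self.tables.angles:
            return
        if tb in _LINEAR_CENTERS:
            theta0 = 180.0
        elif tb in _PLANAR_CENTERS:
            theta0 = round(120.0 + self.rng.uniform(-1.5, 1.5), 2)
        else:
            theta0 = round(109.5 + self.rng.uniform(-1.5, 1.5), 2)
        k = round(self.rng.uniform(33, 70), 2)
        kub = s0 = None
        all_heavy = all(_element(t) != "H" for t in (ta, tb, tc))
        if all_heavy and tb not in _LINEAR_CENTERS:
            kub = round(self.rng.uniform(8, 30), 2)
            s0 = round(2.45 + self.rng.uniform(-0.1, 0.1), 4)
        self.tables.angles[key] = AngleParam(k, theta0, kub, s0)

    def need_dihedral(self, types: tuple[str, str, str, str]) -> None:
        central = frozenset((types[1], types[2]))
        if central in _OMITTED_CENTRALS:
            return  # collinear: upstream never defines it
        if central in _WILDCARD_CENTRALS:
            key = canonical_quad((WILDCARD, types[1], types[2], WILDCARD))
            if key not in self.tables.dihedrals:
                self.tables.dihedrals[key] = [
                    DihedralParam(round(self.rng.uniform(0.1, 0.3), 4), 3, 0.0)
                ]
            return
        key = canonical_quad(types)
        if key in self.tables.dihedrals:
            return
        if central == frozenset(("C", "N")):
            self.tables.dihedrals[key] = [
                DihedralParam(round(self.rng.uniform(1.5, 3.0), 4), 2, 180.0)
            ]
        elif central == frozenset(("CT", "C")):
            self.tables.dihedrals[key] = [
                DihedralParam(round(self.rng.uniform(0.1, 0.3), 4), 1, 0.0),
                DihedralParam(round(self.rng.uniform(0.05, 0.2), 4), 3, 0.0),
            ]
        else:
            self.tables.dihedrals[key] = [
                DihedralParam(round(self.rng.uniform(0.05, 0.3), 4), 3, 0.0)
            ]

    def need_improper(self, types: tuple[str, str, str, str], permuted: bool) -> None:
        if permuted:
            # stored under a permutation of the non-central atoms; the
            # declared order has no entry, on purpose
            key = canonical_quad((types[0], types[1], types[3], types[2]))
        else:
            key = canonical_quad(types)
        if key not in self.tables.impropers:
            self.tables.impropers[key] = ImproperParam(
                round(self.rng.uniform(20, 100), 2), 0.0
            )

    def need_cmap(self, types: tuple[str, ...]) -> None:
        if types in self.tables.cmaps:
            return
        grid = np.round(
            self.rng.uniform(-1.5, 1.5, (CMAP_RESOLUTION, CMAP_RESOLUTION)), 4
        )
        self.tables.cmaps[types] = CmapGrid(CMAP_RESOLUTION, grid)


def _enumerate_needs(
    factory: _ParamFactory,
    context_residues: list[ResidueTopology],
    source: ForceFieldSource,
) -> None:
    for res in context_residues:
        if res.has_lone_pairs:
            continue
        partners = chain_partners(res, source)
        for partner in partners:
            resolve = _type_resolver(res, partner)
            for (sa, na), (sb, nb) in _closure_bonds(res, partner):
                if sa == 0 or sb == 0:
                    blocks = {0: res}
                    ta = (res if sa == 0 else partner).atom(na).type
                    tb = (res if sb == 0 else partner).atom(nb).type
                    factory.need_bond(ta, tb)
            angles, dihedrals = enumerate_residue_terms(res, partner)
            for term in angles:
                types = [resolve(n) for n in term]
                if None not in types:
                    factory.need_angle(*types)  # type: ignore[arg-type]
            for term in dihedrals:
                types = [resolve(n) for n in term]
                if None not in types:
                    factory.need_dihedral(tuple(types))  # type: ignore[arg-type]
        resolve0 = _type_resolver(res, partners[0])
        for quad in res.impropers:
            types = [resolve0(n) for n in quad]
            if None in types:
                continue
            factory.need_improper(
                tuple(types), permuted=(res.name == "IMX")  # type: ignore[arg-type]
            )
        for octet in res.cmaps:
            types = [resolve0(n) for n in octet]
            if None not in types:
                factory.need_cmap(tuple(types))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------


def _render_topology_entry(entry, kind: str) -> list[str]:
    lines = [f"{kind} {entry.name:<6s} {entry.total_charge:8.3f}"]
    group = None
    for a in entry.atoms:
        if a.group_index != group:
            lines.append("GROUP")
            group = a.group_index
        lines.append(f"ATOM {a.name:<5s} {a.type:<6s} {a.charge:8.3f}")
    for a, b in entry.bonds:
        if getattr(entry, "name", "") == "BTY" and {a, b} == {"C2", "C3"}:
            lines.append(f"TRIPLE {a} {b}")
        elif {a, b} == {"O", "C"} or {a, b} == {"OY", "CY"}:
            lines.append(f"DOUBLE {a} {b}")
        else:
            lines.append(f"BOND {a} {b}")
    for quad in entry.impropers:
        lines.append("IMPR " + " ".join(quad))
    for octet in getattr(entry, "cmaps", []):
        lines.append("CMAP " + " ".join(octet[:4]) + " " + " ".join(octet[4:]))
    if kind == "PRES":
        for n in entry.deleted_atoms:
            lines.append(f"DELETE ATOM {n}")
        for quad in entry.deleted_impropers:
            lines.append("DELETE IMPR " + " ".join(quad))
    if getattr(entry, "has_lone_pairs", False):
        lines.append("LONEPAIR COLINEAR LP1 CL1 C1 DIST 1.64 SCAL 0.0")
    if kind == "RESI" and entry.name in ("ALX", "CYX"):
        # analysis-only records the converter must parse and discard
        lines.append("DONOR HN N")
        lines.append("ACCEPTOR O C")
        lines.append("IC -C CA *N HN 1.3551 126.49 180.0 115.42 0.9996")
    return lines


def _render_rtf(residues, patches, masses) -> str:
    lines = ["* synthetic toy topology (ffport fixture generator)", "*", "36  1"]
    for i, (t, m) in enumerate(masses.items(), start=1):
        lines.append(f"MASS  -1  {t:<6s} {m.mass:10.5f} {m.element}")
    lines.append("")
    for res in residues:
        lines.extend(_render_topology_entry(res, "RESI"))
        lines.append("")
    for patch in patches:
        lines.extend(_render_topology_entry(patch, "PRES"))
        lines.append("")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _render_prm(tables: ParameterTables, nbfix: bool = True) -> str:
    lines = ["* synthetic toy parameters (ffport fixture generator)", "*", ""]
    lines.append("BONDS")
    for (a, b), v in sorted(tables.bonds.items()):
        lines.append(f"{a:<6s} {b:<6s} {v.kb:9.3f} {v.b0:8.4f}")
    lines.append("")
    lines.append("ANGLES")
    for (a, b, c), v in sorted(tables.angles.items()):
        tail = f"  {v.kub:7.3f} {v.s0:8.4f}" if v.kub is not None else ""
        lines.append(
            f"{a:<6s} {b:<6s} {c:<6s} {v.ktheta:8.3f} {v.theta0:8.2f}{tail}"
        )
    lines.append("")
    lines.append("DIHEDRALS")
    for key, terms in sorted(tables.dihedrals.items()):
        for t in terms:
            lines.append(
                f"{key[0]:<6s} {key[1]:<6s} {key[2]:<6s} {key[3]:<6s} "
                f"{t.kchi:8.4f} {t.n:2d} {t.delta:7.2f}"
            )
    lines.append("")
    lines.append("IMPROPER")
    for key, v in sorted(tables.impropers.items()):
        lines.append(
            f"{key[0]:<6s} {key[1]:<6s} {key[2]:<6s} {key[3]:<6s} "
            f"{v.kpsi:8.2f}  0 {v.psi0:7.2f}"
        )
    lines.append("")
    if tables.cmaps:
        lines.append("CMAP")
        for key, grid in sorted(tables.cmaps.items()):
            lines.append(" ".join(f"{t:<4s}" for t in key) + f" {grid.resolution}")
            flat = grid.grid.ravel()
            for i in range(0, flat.size, 5):
                lines.append(
                    " ".join(f"{x:10.4f}" for x in flat[i : i + 5])
                )
            lines.append("")
    lines.append("NONBONDED nbxmod 5 atom cdiel fshift vatom vdistance vfswitch -")
    lines.append("cutnb 14.0 ctofnb 12.0 ctonnb 10.0 eps 1.0 e14fac 1.0 wmin 1.5")
    for t, v in sorted(tables.lj.items()):
        tail = ""
        if v.epsilon14 is not None:
            tail = f"   0.0 {v.epsilon14:9.4f} {v.rmin2_14:8.4f}"
        lines.append(f"{t:<6s}  0.0 {v.epsilon:9.4f} {v.rmin2:8.4f}{tail}")
    lines.append("")
    if nbfix and tables.nbfix:
        lines.append("NBFIX")
        for (a, b), v in sorted(tables.nbfix.items()):
            lines.append(f"{a:<6s} {b:<6s} {v.epsilon:9.4f} {v.rmin:8.4f}")
        lines.append("")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _render_str(residues, patches, dup_nbfix: ParameterTables) -> str:
    lines = ["* synthetic toy stream file (ffport fixture generator)", "*", ""]
    lines.append("read rtf card append")
    lines.append("* topology section")
    lines.append("*")
    for res in residues:
        lines.extend(_render_topology_entry(res, "RESI"))
        lines.append("")
    for patch in patches:
        lines.extend(_render_topology_entry(patch, "PRES"))
        lines.append("")
    lines.append("END")
    lines.append("")
    lines.append("read para card flex append")
    lines.append("* parameter section")
    lines.append("*")
    if dup_nbfix.nbfix:
        lines.append("NBFIX")
        for (a, b), v in sorted(dup_nbfix.nbfix.items()):
            lines.append(f"{a:<6s} {b:<6s} {v.epsilon:9.4f} {v.rmin:8.4f}")
    lines.append("END")
    return "\n".join(lines) + "\n"


_BIB = """@article{toyff2024,
  author  = {Doe, Jane and Roe, Richard},
  title   = {A Toy Additive Force Field for Converter Validation},
  journal = {J. Synth. Data},
  volume  = {1},
  pages   = {1--10},
  year    = {2024}
}

@article{toyions2023,
  author  = {Doe, Jane},
  title   = {Monatomic Ions for Toy Force Fields},
  journal = {J. Synth. Data},
  volume  = {0},
  pages   = {11--12},
  year    = {2023}
}
"""


@dataclass
class FixtureFF:
    seed: int
    size: int
    files: dict[str, str] = field(default_factory=dict)
    residue_names: list[str] = field(default_factory=list)

    def write(self, outdir: str) -> str:
        """Write all files; returns the path of the conversion-control file."""
        os.makedirs(outdir, exist_ok=True)
        for name, text in self.files.items():
            with open(os.path.join(outdir, name), "w") as fh:
                fh.write(text)
        return os.path.join(outdir, "ffport.in")


def generate_fixture_ff(seed: int, size: int = 10) -> FixtureFF:
    """Deterministic synthetic force-field file set (2-10 residues)."""
    if not 2 <= size <= 10:
        raise ValueError("size must be between 2 and 10 residues")
    rng = np.random.default_rng(seed)
    all_residues = _make_residues()
    residues = all_residues[:size]
    names = {r.name for r in residues}
    patches = _make_patches()

    # classes: the first three templates are protein-like, the rest generic
    prot_names = {"ALX", "CYX", "GLYD"}
    rtf_residues = [r for r in residues if r.name in prot_names]
    str_residues = [r for r in residues if r.name not in prot_names]
    rtf_patches = [p for p in patches if p.name in ("NTE", "CTE", "DSX")]
    str_patches = [p for p in patches if p.name == "OME" and "ETX" in names]

    source = ForceFieldSource()
    for r in residues:
        rr = r.copy()
        rr.group = "prot" if r.name in prot_names else "cgenff"
        rr.chainable = _residue_is_chainable(rr)
        source.residues[rr.name] = rr
    for p in patches:
        source.patches[p.name] = p

    factory = _ParamFactory(rng)
    source.params.masses = factory.tables.masses

    # context residues: everything retained, plus the patched and
    # terminus-modified variants whose parameter needs must be covered
    from .patching import apply_patch, split_crosslink_patch

    context = [r for r in source.residues.values() if not r.has_lone_pairs]
    if "ETX" in names:
        context.append(apply_patch(source.residues["ETX"],
                                   source.patches["OME"], "ETXM"))
    if "CYX" in names:
        half = split_crosslink_patch(source.patches["DSX"], 1)
        context.append(apply_patch(source.residues["CYX"], half, "CYX2"))
    for base in [
        r for r in source.residues.values()
        if r.chainable and r.group == "prot" and not r.has_lone_pairs
    ]:
        for pname in ("NTE", "CTE"):
            context.append(
                apply_patch(base, source.patches[pname], f"{base.name}_{pname}")
            )
    _enumerate_needs(factory, context, source)

    config_lines = [
        "# conversion control file (synthetic fixture)",
        "name toyff",
        "description Synthetic toy port of a CHARMM-format force field",
        "input rtf prot toy_prot.rtf",
        "input prm prot toy_par.prm",
        "input str cgenff toy_extra.str",
    ]
    if "ETX" in names:
        config_lines.append("patch ETX OME ETXM")
    if "CYX" in names:
        config_lines.append("patch CYX DSX CYX2")
    config_lines += [
        "terminus NTE N",
        "terminus CTE C",
        "terminaldelete OXT",
        "citations toy_refs.bib",
        "cite ALX toyff2024",
    ]
    if "SOD" in names:
        config_lines += ["copyresidues SOD NA", "cite SOD toyions2023"]
    config_lines += [
        "watermodels tip3p_charmm tip3p",
        "pairtypes overrides",
    ]

    fx = FixtureFF(seed=seed, size=size, residue_names=[r.name for r in residues])
    fx.files["toy_prot.rtf"] = _render_rtf(
        rtf_residues, rtf_patches, factory.tables.masses
    )
    fx.files["toy_par.prm"] = _render_prm(factory.tables)
    dup = ParameterTables()
    if "SOD" in names:
        key = canonical_pair(("SOD", "OH1"))
        dup.nbfix[key] = factory.tables.nbfix[key]
    fx.files["toy_extra.str"] = _render_str(str_residues, str_patches, dup)
    fx.files["ffport.in"] = "\n".join(config_lines) + "\n"
    fx.files["toy_refs.bib"] = _BIB
    return fx
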