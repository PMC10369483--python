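"""Single-point energy evaluation under both functional-form conventions.

Two independent evaluators score the *same* atomic configuration: one
directly from the source-format parameter tables (AKMA units, ``V = K x^2``
harmonics, epsilon/R_min Lennard-Jones), one from the converted parameter set
(SI-derived units, ``V = k x^2 / 2`` harmonics, sigma/epsilon LJ).  If the
conversion is correct, every per-term energy satisfies

    E_converted [kJ/mol] = 4.184 * E_source [kcal/mol]

to floating-point accuracy.  Evaluation is in vacuum with no cutoffs, which
removes neighbor-list artifacts from the comparison by construction.

CMAP is interpolated bilinearly in both evaluators; since conversion is a
pure scaling, the identity holds for any interpolant as long as both sides
use the same one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .geometry import enumerate_angles_dihedrals
from .model import (
    FFError,
    WILDCARD,
    ParameterTables,
    ResidueTopology,
    canonical_pair,
    canonical_quad,
    canonical_triplet,
)
from .param_convert import GmxParameterSet, combine_lorentz_berthelot
from .units import (
    A_TO_NM,
    COULOMB_KCAL_A,
    COULOMB_KJ_NM,
    DEG_TO_RAD,
    KCAL_TO_KJ,
    TWO_POW_SIXTH,
)

TERM_NAMES = (
    "bond", "angle", "urey_bradley", "proper", "improper",
    "lj", "lj14", "coulomb", "cmap",
)


@dataclass
class Configuration:
    """One molecular configuration shared by both evaluators.

    Coordinates are stored in Angstrom; the converted-frame evaluator sees
    the identical geometry scaled by 0.1.  Bonded terms are index tuples into
    the atom arrays; 1-2 and 1-3 pairs are excluded from nonbonded sums and
    1-4 pairs use the dedicated 1-4 Lennard-Jones parameters.
    """

    names: list[str]
    types: list[str]
    charges: np.ndarray
    coords_a: np.ndarray  # (N, 3) Angstrom
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    cmaps: list[tuple[int, ...]] = field(default_factory=list)
    exclusions: set[frozenset[int]] = field(default_factory=set)
    pairs14: list[tuple[int, int]] = field(default_factory=list)

    @property
    def coords_nm(self) -> np.ndarray:
        return self.coords_a * A_TO_NM

    @property
    def n_atoms(self) -> int:
        return len(self.names)


def build_configuration(
    residues: Sequence[ResidueTopology],
    coords_a: Sequence[np.ndarray],
) -> Configuration:
    """Assemble a configuration from one or more residue molecules.

    Bonded terms come from each residue's internal connectivity (chain
    prefixes are ignored; every molecule is a standalone entity here);
    angle/dihedral lists are enumerated from the bond graph exactly as the
    topology builder would.  No exclusions exist between molecules.
    """
    names: list[str] = []
    types: list[str] = []
    charges: list[float] = []
    xyz: list[np.ndarray] = []
    cfg = Configuration(names, types, np.zeros(0), np.zeros((0, 3)))
    offset = 0
    for res, crd in zip(residues, coords_a):
        index = {a.name: offset + i for i, a in enumerate(res.atoms)}
        names.extend(f"{res.name}:{a.name}" for a in res.atoms)
        types.extend(a.type for a in res.atoms)
        charges.extend(a.charge for a in res.atoms)
        xyz.append(np.asarray(crd, dtype=float))
        internal = res.internal_bonds()
        cfg.bonds.extend((index[a], index[b]) for a, b in internal)
        ang, dih = enumerate_angles_dihedrals(internal)
        cfg.angles.extend(tuple(index[x] for x in t) for t in ang)
        cfg.dihedrals.extend(tuple(index[x] for x in t) for t in dih)
        for quad in res.impropers:
            if all(q in index for q in quad):
                cfg.impropers.append(tuple(index[q] for q in quad))
        for octet in res.cmaps:
            if all(q in index for q in octet):
                cfg.cmaps.append(tuple(index[q] for q in octet))
        g = nx.Graph(internal)
        g.add_nodes_from(a.name for a in res.atoms)
        for a_name, dists in nx.all_pairs_shortest_path_length(g, cutoff=3):
            for b_name, d in dists.items():
                i, j = index[a_name], index[b_name]
                if i >= j:
                    continue
                if d in (1, 2):
                    cfg.exclusions.add(frozenset((i, j)))
                elif d == 3:
                    cfg.pairs14.append((i, j))
        offset += len(res.atoms)
    # a path of exactly 3 bonds that is also reachable in fewer is excluded
    cfg.pairs14 = sorted(
        {(i, j) for i, j in cfg.pairs14 if frozenset((i, j)) not in cfg.exclusions}
    )
    cfg.charges = np.array(charges, dtype=float)
    cfg.coords_a = np.vstack(xyz) if xyz else np.zeros((0, 3))
    return cfg


# ---------------------------------------------------------------------------
# geometry kernels (Angstrom or nm; unit-agnostic where possible)
# ---------------------------------------------------------------------------


def _dist(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[i] - x[j]))


def _angle_rad(x: np.ndarray, i: int, j: int, k: int) -> float:
    a = x[i] - x[j]
    b = x[k] - x[j]
    cosv = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.acos(max(-1.0, min(1.0, cosv)))


def _dihedral_rad(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2)))


def _wrap_angle_diff(a: float, b: float) -> float:
    """Smallest signed difference a-b for angles in radians."""
    d = a - b
    while d > math.pi:
        d -= 2 * math.pi
    while d < -math.pi:
        d += 2 * math.pi
    return d


def bilinear_periodic(grid: np.ndarray, phi_deg: float, psi_deg: float) -> float:
    """Bilinear interpolation on a periodic (-180..180) square grid whose
    [0, 0] corner sits at (-180, -180)."""
    res = grid.shape[0]
    spacing = 360.0 / res
    u = (phi_deg + 180.0) / spacing
    v = (psi_deg + 180.0) / spacing
    i0 = int(math.floor(u)) % res
    j0 = int(math.floor(v)) % res
    fu = u - math.floor(u)
    fv = v - math.floor(v)
    i1 = (i0 + 1) % res
    j1 = (j0 + 1) % res
    return float(
        grid[i0, j0] * (1 - fu) * (1 - fv)
        + grid[i1, j0] * fu * (1 - fv)
        + grid[i0, j1] * (1 - fu) * fv
        + grid[i1, j1] * fu * fv
    )


def _find_improper(params_lookup, types: Sequence[str]):
    """Exact/wildcard first, then any permutation of the non-central atoms
    (the source engine's tolerance, emulated identically on both sides)."""
    import itertools

    hit, _w = params_lookup(types)
    if hit is not None:
        return hit
    for perm in itertools.permutations(types[1:4]):
        hit, _w = params_lookup((types[0],) + perm)
        if hit is not None:
            return hit
    return None


# ---------------------------------------------------------------------------
# evaluator: source (AKMA) functional form
# ---------------------------------------------------------------------------


def energy_charmm_form(
    config: Configuration,
    params: ParameterTables,
    dummy_dihedrals: Optional[set[tuple[str, str, str, str]]] = None,
) -> dict[str, float]:
    """Per-term energies in kcal/mol from the source parameter tables."""
    dummy_dihedrals = dummy_dihedrals or set()
    x = config.coords_a
    t = config.types
    e = {k: 0.0 for k in TERM_NAMES}

    for i, j in config.bonds:
        p = params.lookup_bond(t[i], t[j])
        if p is None:
            raise FFError(f"no bond parameter for ({t[i]},{t[j]})")
        e["bond"] += p.kb * (_dist(x, i, j) - p.b0) ** 2

    for i, j, k in config.angles:
        p = params.lookup_angle(t[i], t[j], t[k])
        if p is None:
            raise FFError(f"no angle parameter for ({t[i]},{t[j]},{t[k]})")
        dth = _angle_rad(x, i, j, k) - p.theta0 * DEG_TO_RAD
        e["angle"] += p.ktheta * dth * dth
        if p.kub is not None and p.s0 is not None:
            e["urey_bradley"] += p.kub * (_dist(x, i, k) - p.s0) ** 2

    for quad in config.dihedrals:
        types = tuple(t[i] for i in quad)
        terms, _wild = params.lookup_dihedral(types)
        if terms is None:
            if canonical_quad(types) in dummy_dihedrals:
                continue  # zero-force dummy: exactly 0 by definition
            raise FFError(f"no dihedral parameter for {types}")
        phi = _dihedral_rad(x, *quad)
        for p in terms:
            e["proper"] += p.kchi * (1.0 + math.cos(p.n * phi - p.delta * DEG_TO_RAD))

    for quad in config.impropers:
        types = tuple(t[i] for i in quad)
        p = _find_improper(params.lookup_improper, types)
        if p is None:
            raise FFError(f"no improper parameter for {types}")
        dpsi = _wrap_angle_diff(_dihedral_rad(x, *quad), p.psi0 * DEG_TO_RAD)
        e["improper"] += p.kpsi * dpsi * dpsi

    for octet in config.cmaps:
        types = tuple(t[i] for i in octet)
        grid = params.cmaps.get(types)
        if grid is None:
            raise FFError(f"no CMAP parameter for {types}")
        phi = _dihedral_rad(x, *octet[0:4]) / DEG_TO_RAD
        psi = _dihedral_rad(x, *octet[4:8]) / DEG_TO_RAD
        e["cmap"] += bilinear_periodic(grid.grid, phi, psi)

    # nonbonded
    pairs14 = set(config.pairs14)
    n = config.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in config.exclusions:
                continue
            r = _dist(x, i, j)
            is14 = (i, j) in pairs14
            li, lj_ = params.lj[t[i]], params.lj[t[j]]
            nb = params.lookup_nbfix(t[i], t[j])
            if nb is not None and not is14:
                eps = abs(nb.epsilon)
                rmin = nb.rmin
            else:
                if is14:
                    ei = abs(li.epsilon14 if li.epsilon14 is not None else li.epsilon)
                    ri = li.rmin2_14 if li.rmin2_14 is not None else li.rmin2
                    ej = abs(lj_.epsilon14 if lj_.epsilon14 is not None else lj_.epsilon)
                    rj = lj_.rmin2_14 if lj_.rmin2_14 is not None else lj_.rmin2
                else:
                    ei, ri = abs(li.epsilon), li.rmin2
                    ej, rj = abs(lj_.epsilon), lj_.rmin2
                eps = math.sqrt(ei * ej)
                rmin = ri + rj
            ratio6 = (rmin / r) ** 6
            contrib = eps * (ratio6 * ratio6 - 2.0 * ratio6)
            e["lj14" if is14 else "lj"] += contrib
            e["coulomb"] += (
                COULOMB_KCAL_A * config.charges[i] * config.charges[j] / r
            )
    return e


# ---------------------------------------------------------------------------
# evaluator: converted (GROMACS) functional form
# ---------------------------------------------------------------------------


def energy_gmx_form(
    config: Configuration,
    gmx: GmxParameterSet,
    dummy_dihedrals: Optional[set[tuple[str, str, str, str]]] = None,
) -> dict[str, float]:
    """Per-term energies in kJ/mol from the converted parameter set."""
    dummy_dihedrals = dummy_dihedrals or set()
    x = config.coords_nm
    t = config.types
    e = {k: 0.0 for k in TERM_NAMES}

    def _dihedral_lookup(types):
        key = canonical_quad(types)
        hit = gmx.dihedraltypes.get(key)
        if hit is not None:
            return hit
        wkey = canonical_quad((WILDCARD, types[1], types[2], WILDCARD))
        return gmx.dihedraltypes.get(wkey)

    def _improper_lookup(types):
        key = canonical_quad(types)
        hit = gmx.impropertypes.get(key)
        if hit is not None:
            return hit, False
        wkey = canonical_quad((types[0], WILDCARD, WILDCARD, types[3]))
        return gmx.impropertypes.get(wkey), True

    for i, j in config.bonds:
        key = canonical_pair((t[i], t[j]))
        if key not in gmx.bondtypes:
            raise FFError(f"no bondtype for {key}")
        b0, kb = gmx.bondtypes[key]
        e["bond"] += 0.5 * kb * (_dist(x, i, j) - b0) ** 2

    for i, j, k in config.angles:
        key = canonical_triplet((t[i], t[j], t[k]))
        if key not in gmx.angletypes:
            raise FFError(f"no angletype for {key}")
        theta0, kth, ub0, kub = gmx.angletypes[key]
        dth = _angle_rad(x, i, j, k) - theta0 * DEG_TO_RAD
        e["angle"] += 0.5 * kth * dth * dth
        if kub:
            e["urey_bradley"] += 0.5 * kub * (_dist(x, i, k) - ub0) ** 2

    for quad in config.dihedrals:
        types = tuple(t[i] for i in quad)
        terms = _dihedral_lookup(types)
        if terms is None:
            if canonical_quad(types) in dummy_dihedrals:
                continue
            raise FFError(f"no dihedraltype for {types}")
        phi = _dihedral_rad(x, *quad)
        for delta, kchi, n in terms:
            e["proper"] += kchi * (1.0 + math.cos(n * phi - delta * DEG_TO_RAD))

    for quad in config.impropers:
        types = tuple(t[i] for i in quad)
        hit = _find_improper(_improper_lookup, types)
        if hit is None:
            raise FFError(f"no impropertype for {types}")
        psi0, kpsi = hit
        dpsi = _wrap_angle_diff(_dihedral_rad(x, *quad), psi0 * DEG_TO_RAD)
        e["improper"] += 0.5 * kpsi * dpsi * dpsi

    for octet in config.cmaps:
        types = tuple(t[i] for i in octet)
        grid = gmx.cmaptypes.get(types)
        if grid is None:
            raise FFError(f"no cmaptype for {types}")
        phi = _dihedral_rad(x, *octet[0:4]) / DEG_TO_RAD
        psi = _dihedral_rad(x, *octet[4:8]) / DEG_TO_RAD
        e["cmap"] += bilinear_periodic(grid.grid, phi, psi)

    pairs14 = set(config.pairs14)
    n = config.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in config.exclusions:
                continue
            r = _dist(x, i, j)
            is14 = (i, j) in pairs14
            ai, aj = gmx.atomtypes[t[i]], gmx.atomtypes[t[j]]
            key = canonical_pair((t[i], t[j]))
            if is14:
                if key in gmx.pairtypes:
                    sigma, eps = gmx.pairtypes[key]
                else:  # automatic pair generation from the combination rule
                    sigma, eps = combine_lorentz_berthelot(
                        (ai.sigma, ai.epsilon), (aj.sigma, aj.epsilon)
                    )
            elif key in gmx.nonbond_params:
                sigma, eps = gmx.nonbond_params[key]
            else:
                sigma, eps = combine_lorentz_berthelot(
                    (ai.sigma, ai.epsilon), (aj.sigma, aj.epsilon)
                )
            sr6 = (sigma / r) ** 6
            contrib = 4.0 * eps * (sr6 * sr6 - sr6)
            e["lj14" if is14 else "lj"] += contrib
            e["coulomb"] += (
                COULOMB_KJ_NM * config.charges[i] * config.charges[j] / r
            )
    return e


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


@dataclass
class EnergyReport:
    e_charmm: dict[str, float]  # kcal/mol
    e_gmx: dict[str, float]  # kJ/mol
    abs_diff: dict[str, float]  # |E_gmx - 4.184 E_charmm|, kJ/mol
    rel_diff: dict[str, float]
    tolerance: float
    passed: bool

    def worst_term(self) -> tuple[str, float]:
        term = max(self.rel_diff, key=lambda k: self.rel_diff[k])
        return term, self.rel_diff[term]

    def failing_terms(self) -> list[str]:
        return [k for k, v in self.rel_diff.items() if v > self.tolerance]


def compare(
    config: Configuration,
    params: ParameterTables,
    gmx: GmxParameterSet,
    dummy_dihedrals: Optional[set[tuple[str, str, str, str]]] = None,
    tolerance: float = 1e-9,
) -> EnergyReport:
    """Score one configuration with both evaluators and report per-term
    absolute and relative differences on the kJ/mol scale."""
    ec = energy_charmm_form(config, params, dummy_dihedrals)
    eg = energy_gmx_form(config, gmx, dummy_dihedrals)
    abs_diff: dict[str, float] = {}
    rel_diff: dict[str, float] = {}
    for k in TERM_NAMES:
        scaled = ec[k] * KCAL_TO_KJ
        abs_diff[k] = abs(eg[k] - scaled)
        denom = max(abs(scaled), abs(eg[k]))
        rel_diff[k] = abs_diff[k] / denom if denom > 0 else 0.0
    passed = all(v <= tolerance for v in rel_diff.values())
    return EnergyReport(ec, eg, abs_diff, rel_diff, tolerance, passed)


# ---------------------------------------------------------------------------
# coordinate construction from perceived geometry
# ---------------------------------------------------------------------------


def build_coordinates(
    residue: ResidueTopology,
    params: ParameterTables,
    rng: np.random.Generator,
    jitter: float = 0.04,
) -> np.ndarray:
    """Plausible (not minimized) 3-D coordinates in Angstrom.

    Atoms are placed breadth-first with bond lengths and valence angles drawn
    from the parameter tables (perturbed by a small relative jitter so that
    every energy term is strictly positive) and random torsions.  Collinear
    equilibrium angles are bent slightly to keep torsion placement defined.
    """
    order: list[str] = []
    parent: dict[str, Optional[str]] = {}
    adj: dict[str, list[str]] = {a.name: [] for a in residue.atoms}
    for a, b in residue.internal_bonds():
        adj[a].append(b)
        adj[b].append(a)
    for start in residue.atom_names:
        if start in order:
            continue
        queue = [start]
        parent[start] = None
        while queue:
            cur = queue.pop(0)
            if cur in order:
                continue
            order.append(cur)
            for nb in adj[cur]:
                if nb not in order and nb not in queue:
                    parent[nb] = cur
                    queue.append(nb)

    tpe = {a.name: a.type for a in residue.atoms}
    pos: dict[str, np.ndarray] = {}

    def bond_length(a: str, b: str) -> float:
        p = params.lookup_bond(tpe[a], tpe[b])
        b0 = p.b0 if p is not None else 1.5
        return b0 * (1.0 + jitter * (rng.random() - 0.5))

    def angle_deg(a: str, b: str, c: str) -> float:
        p = params.lookup_angle(tpe[a], tpe[b], tpe[c])
        th = p.theta0 if p is not None else 111.0
        th = th * (1.0 + 0.5 * jitter * (rng.random() - 0.5))
        return min(th, 178.0)

    for name in order:
        par = parent[name]
        if par is None:
            pos[name] = rng.normal(scale=6.0, size=3)  # separate fragments
            continue
        gp = parent[par]
        b = bond_length(name, par)
        if gp is None:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos[name] = pos[par] + b * direction
            continue
        theta = angle_deg(name, par, gp) * DEG_TO_RAD
        ggp = parent[gp]
        if ggp is None or ggp not in pos:
            ref = rng.normal(size=3)
        else:
            ref = pos[ggp] - pos[gp]
        phi = rng.uniform(-math.pi, math.pi)
        # local frame at the parent, NeRF-style placement
        bc = pos[par] - pos[gp]
        bc /= np.linalg.norm(bc)
        n_vec = np.cross(ref, bc)
        norm = np.linalg.norm(n_vec)
        if norm < 1e-8:
            tmp = rng.normal(size=3)
            n_vec = np.cross(tmp, bc)
            norm = np.linalg.norm(n_vec)
        n_vec /= norm
        m_vec = np.cross(n_vec, bc)
        d = np.array(
            [
                -b * math.cos(theta),
                b * math.sin(theta) * math.cos(phi),
                b * math.sin(theta) * math.sin(phi),
            ]
        )
        pos[name] = pos[par] + d[0] * bc + d[1] * m_vec + d[2] * n_vec
    return np.vstack([pos[a.name] for a in residue.atoms])
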