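"""Conversion of interaction parameters from AKMA units to GROMACS units.

The arithmetic is deliberately plain: kcal -> kJ with the exact thermochemical
factor, Angstrom -> nm, and a factor of 2 on every harmonic force constant
because CHARMM writes ``V = K (x - x0)^2`` where GROMACS writes
``V = (1/2) k (x - x0)^2``.  Periodic dihedrals share the same functional form
in both codes and get no factor of 2.  Lennard-Jones ``R_min/2`` becomes
``sigma`` via ``R_min = 2^(1/6) sigma``.

Equilibrium angle positions stay in degrees (the downstream file convention)
while their force constants are per rad^2; this asymmetry is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    CmapGrid,
    FFError,
    LJParam,
    ParameterTables,
    canonical_pair,
)
from .units import A_TO_NM, KCAL_TO_KJ, TWO_POW_SIXTH

_LENGTH_BASED = {"bond": True, "angle": False, "urey_bradley": True, "improper": False}


def convert_harmonic(K: float, x0: float, kind: str) -> tuple[float, float]:
    """CHARMM harmonic (K, x0) -> GROMACS (k, x0).

    ``k = 2 * K * 4.184``, times 100 for length-based terms (A^-2 -> nm^-2);
    lengths go A -> nm, angle positions stay in degrees.
    """
    try:
        length_based = _LENGTH_BASED[kind]
    except KeyError:
        raise FFError(f"unknown harmonic kind {kind!r}") from None
    if K < 0:
        raise FFError(f"negative harmonic force constant {K} ({kind})")
    k = 2.0 * K * KCAL_TO_KJ * (100.0 if length_based else 1.0)
    return (k, x0 * A_TO_NM) if length_based else (k, x0)


def convert_dihedral(kchi: float, n: int, delta: float) -> tuple[float, float, int]:
    """Periodic dihedral: force constant kcal -> kJ; n and delta unchanged."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise FFError(f"dihedral multiplicity must be a positive integer, got {n!r}")
    return (delta, kchi * KCAL_TO_KJ, int(n))


def convert_lj(epsilon: float, rmin2: float) -> tuple[float, float]:
    """(epsilon as printed, R_min/2 in A) -> (sigma nm, epsilon kJ/mol)."""
    if rmin2 <= 0:
        raise FFError(f"R_min/2 must be positive, got {rmin2}")
    sigma = 2.0 * rmin2 / TWO_POW_SIXTH * A_TO_NM
    return (sigma, abs(epsilon) * KCAL_TO_KJ)


def convert_nbfix_entry(epsilon: float, rmin: float) -> tuple[float, float]:
    """NBFIX rows list the *full* R_min, not R_min/2."""
    if rmin <= 0:
        raise FFError(f"NBFIX R_min must be positive, got {rmin}")
    sigma = rmin / TWO_POW_SIXTH * A_TO_NM
    return (sigma, abs(epsilon) * KCAL_TO_KJ)


def convert_cmap(grid: np.ndarray) -> np.ndarray:
    """Elementwise kcal -> kJ; shape checked square."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise FFError(f"CMAP grid must be square, got shape {grid.shape}")
    return grid * KCAL_TO_KJ


def combine_lorentz_berthelot(
    lj_a: tuple[float, float], lj_b: tuple[float, float]
) -> tuple[float, float]:
    """(sigma, epsilon) pair combination: arithmetic sigma, geometric epsilon."""
    (sa, ea), (sb, eb) = lj_a, lj_b
    return (0.5 * (sa + sb), float(np.sqrt(ea * eb)))


# ---------------------------------------------------------------------------
# converted containers
# ---------------------------------------------------------------------------


@dataclass
class GmxAtomType:
    mass: float
    atomic_number: int
    sigma: float
    epsilon: float
    sigma14: Optional[float] = None
    epsilon14: Optional[float] = None


@dataclass
class GmxParameterSet:
    """All converted parameters, GROMACS units and conventions."""

    bondtypes: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # -> (b0 nm, kb)
    angletypes: dict[
        tuple[str, str, str], tuple[float, float, float, float]
    ] = field(default_factory=dict)  # -> (theta0 deg, ktheta, ub0 nm, kub)
    dihedraltypes: dict[
        tuple[str, str, str, str], list[tuple[float, float, int]]
    ] = field(default_factory=dict)  # -> [(delta, kchi, n)]
    impropertypes: dict[tuple[str, str, str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # -> (psi0 deg, kpsi)
    atomtypes: dict[str, GmxAtomType] = field(default_factory=dict)
    pairtypes: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # -> (sigma14, eps14)
    nonbond_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # NBFIX -> (sigma, eps)
    cmaptypes: dict[tuple[str, ...], CmapGrid] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "bondtypes": len(self.bondtypes),
            "angletypes": len(self.angletypes),
            "dihedraltypes": sum(len(v) for v in self.dihedraltypes.values()),
            "impropertypes": len(self.impropertypes),
            "atomtypes": len(self.atomtypes),
            "pairtypes": len(self.pairtypes),
            "nonbond_params": len(self.nonbond_params),
            "cmaptypes": len(self.cmaptypes),
        }


def effective_lj14(lj: LJParam) -> tuple[float, float]:
    """Converted (sigma, epsilon) to use for 1-4 pairs: the dedicated 1-4
    set when present, else the standard one."""
    if lj.epsilon14 is not None and lj.rmin2_14 is not None:
        return convert_lj(lj.epsilon14, lj.rmin2_14)
    return convert_lj(lj.epsilon, lj.rmin2)


def build_pairtypes(
    lj_table: dict[str, LJParam], mode: str = "overrides"
) -> dict[tuple[str, str], tuple[float, float]]:
    """1-4 pair parameters under the ``pairtypes`` directive.

    ``mode='full'`` enumerates every unordered pair of atom types
    (N(N+1)/2 entries).  ``mode='overrides'`` emits only pairs where at least
    one member carries dedicated 1-4 values; the remaining pairs are covered
    by the writer's automatic pair generation from the combination rule.
    """
    if mode not in ("full", "overrides"):
        raise FFError(f"unknown pairtypes mode {mode!r}")
    out: dict[tuple[str, str], tuple[float, float]] = {}
    types = list(lj_table)
    for i, ta in enumerate(types):
        for tb in types[i:]:
            a, b = lj_table[ta], lj_table[tb]
            if mode == "overrides" and a.epsilon14 is None and b.epsilon14 is None:
                continue
            out[canonical_pair((ta, tb))] = combine_lorentz_berthelot(
                effective_lj14(a), effective_lj14(b)
            )
    return out


def convert_parameters(
    tables: ParameterTables,
    pairtypes_mode: str = "overrides",
    element_number=None,
) -> GmxParameterSet:
    """Convert a full CHARMM parameter table set; entry counts are preserved
    per category (pairtypes are derived, not converted)."""
    from .units import atomic_number as _default_z

    znum = element_number or _default_z
    out = GmxParameterSet()
    for key, v in tables.bonds.items():
        kb, b0 = convert_harmonic(v.kb, v.b0, "bond")
        out.bondtypes[key] = (b0, kb)
    for key, v in tables.angles.items():
        kt, theta0 = convert_harmonic(v.ktheta, v.theta0, "angle")
        if v.kub is not None and v.s0 is not None:
            kub, ub0 = convert_harmonic(v.kub, v.s0, "urey_bradley")
        else:
            kub, ub0 = 0.0, 0.0
        out.angletypes[key] = (theta0, kt, ub0, kub)
    for key, terms in tables.dihedrals.items():
        seen: set[int] = set()
        for t in terms:
            if t.n in seen:
                raise FFError(f"duplicate multiplicity {t.n} for dihedral {key}")
            seen.add(t.n)
            out.dihedraltypes.setdefault(key, []).append(
                convert_dihedral(t.kchi, t.n, t.delta)
            )
    for key, v in tables.impropers.items():
        kp, psi0 = convert_harmonic(v.kpsi, v.psi0, "improper")
        out.impropertypes[key] = (psi0, kp)
    for t, lj in tables.lj.items():
        sigma, eps = convert_lj(lj.epsilon, lj.rmin2)
        mass = tables.masses[t].mass if t in tables.masses else 0.0
        element = tables.masses[t].element if t in tables.masses else ""
        s14 = e14 = None
        if lj.epsilon14 is not None and lj.rmin2_14 is not None:
            s14, e14 = convert_lj(lj.epsilon14, lj.rmin2_14)
        out.atomtypes[t] = GmxAtomType(
            mass=mass,
            atomic_number=znum(element),
            sigma=sigma,
            epsilon=eps,
            sigma14=s14,
            epsilon14=e14,
        )
    out.pairtypes = build_pairtypes(tables.lj, mode=pairtypes_mode)
    for key, v in tables.nbfix.items():
        out.nonbond_params[key] = convert_nbfix_entry(v.epsilon, v.rmin)
    for key, grid in tables.cmaps.items():
        out.cmaptypes[key] = CmapGrid(grid.resolution, convert_cmap(grid.grid))
    return out


# ---------------------------------------------------------------------------
# inverse conversion (invertibility checks)
# ---------------------------------------------------------------------------


def invert_harmonic(k: float, x0: float, kind: str) -> tuple[float, float]:
    length_based = _LENGTH_BASED[kind]
    K = k / (2.0 * KCAL_TO_KJ * (100.0 if length_based else 1.0))
    return (K, x0 / A_TO_NM) if length_based else (K, x0)


def invert_lj(sigma: float, epsilon: float) -> tuple[float, float]:
    """-> (epsilon kcal, printed negative; R_min/2 in A)."""
    rmin2 = sigma * TWO_POW_SIXTH / 2.0 / A_TO_NM
    return (-epsilon / KCAL_TO_KJ, rmin2)
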