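"""Unit conventions shared by the converter and the energy evaluators.

The CHARMM side works in the AKMA system (Angstrom, kcal/mol, degrees for
printed equilibrium angles); the GROMACS side works in nm and kJ/mol.  The
thermochemical calorie (1 kcal = 4.184 kJ exactly) is used throughout, which
is the convention of both engines.
"""

import math

#: exact thermochemical calorie
KCAL_TO_KJ = 4.184

#: Angstrom -> nanometre
A_TO_NM = 0.1

#: 2^(1/6); R_min = sigma * 2^(1/6) for the 12-6 Lennard-Jones potential
TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)

#: electric conversion factor, kJ mol^-1 nm e^-2 (GROMACS convention)
COULOMB_KJ_NM = 138.935458

#: the same physical constant expressed in kcal mol^-1 Angstrom e^-2.
#: Both single-point evaluators use this one constant so that the Coulomb
#: term obeys the exact E_kJ = 4.184 * E_kcal identity; CHARMM's historical
#: rounded value (332.0716) differs from it by ~3e-5 relative.
COULOMB_KCAL_A = COULOMB_KJ_NM / KCAL_TO_KJ * 10.0

DEG_TO_RAD = math.pi / 180.0

#: atoms lighter than this (amu) are treated as hydrogen
HYDROGEN_MASS_CUTOFF = 3.5

# minimal element -> atomic number table; covers the elements appearing in
# additive biomolecular force fields (plus a zero entry for massless sites)
ATOMIC_NUMBERS = {
    "": 0, "LP": 0, "D": 0,
    "H": 1, "HE": 2, "LI": 3, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9,
    "NE": 10, "NA": 11, "MG": 12, "AL": 13, "SI": 14, "P": 15, "S": 16,
    "CL": 17, "K": 19, "CA": 20, "CR": 24, "MN": 25, "FE": 26, "CO": 27,
    "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "RB": 37, "CD": 48,
    "I": 53, "CS": 55, "BA": 56,
}


def atomic_number(element: str) -> int:
    """Atomic number for an element symbol; unknown symbols map to 0."""
    return ATOMIC_NUMBERS.get(element.upper(), 0)
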