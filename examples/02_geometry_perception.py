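"""Perceive local internal geometry from bonded connectivity alone.

No coordinates are involved: valence angles and proper dihedrals are
enumerated as simple paths through the bond graph (crossing the polymer
junction for chainable residues), equilibrium values are attached from the
parameter tables, and each hydrogen-bearing heavy atom is classified as
planar / tetrahedral / linear / threefold.
"""

import tempfile

from ffport.charmm_io import parse_config
from ffport.fixtures import generate_fixture_ff
from ffport.geometry import perceive_residue
from ffport.pipeline import load_and_merge

with tempfile.TemporaryDirectory() as tmp:
    config_path = generate_fixture_ff(seed=1, size=10).write(tmp)
    merged = load_and_merge(parse_config(config_path))

for name in ("ALX", "BTY"):
    res = merged.residues[name]
    geom = perceive_residue(res, merged)
    print(f"== {name} (chainable: {res.chainable}) ==")
    print(f"  angles: {len(geom.angles)}, dihedrals: {len(geom.dihedrals)}, "
          f"missing dihedrals: {len(geom.missing_dihedrals)}")
    junction = [t for t in geom.angles if any(n[0] in "+-" for n in t)]
    if junction:
        print(f"  junction-crossing angles: {junction}")
    for atom, cls in geom.classification.items():
        print(f"  {atom}: {cls}, theta0 of incident angles: "
              + ", ".join(
                  f"{th:.1f}" for t, th in geom.angles.items()
                  if th is not None and t[1].lstrip('+-') == atom
              ))
# BTY's missing dihedral crosses the 180-degree triple-bond axis: the
# torsion is geometrically undefined, which the fixup stage repairs later.
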