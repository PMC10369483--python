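"""Synthesize hydrogen-addition rules from perceived geometry.

Each block says: construct `h_count` hydrogens named from `stem` on the
first control atom, using the geometric recipe of `rule` (1 = one planar H,
2 = dihedral-defined single H, 3 = two planar H, 4 = three tetrahedral H,
5 = one tetrahedral H, 6 = two tetrahedral H), anchored on the control
atoms.
"""

import tempfile

from ffport.fixtures import generate_fixture_ff
from ffport.pipeline import run_conversion_from_file

with tempfile.TemporaryDirectory() as tmp:
    config_path = generate_fixture_ff(seed=1, size=10).write(tmp)
    result = run_conversion_from_file(config_path)

for cls, rules in sorted(result.hdb_rules.items()):
    print(f"== class {cls} ==")
    for rule in rules:
        if not rule.blocks:
            continue
        print(f"{rule.residue}")
        for b in rule.blocks:
            print(f"  {b.h_count} x {b.name_stem:<4s} rule {b.rule_code}  "
                  f"controls: {' '.join(b.control_atoms)}")
if result.attention:
    print("\nmanual attention needed:")
    for item in result.attention:
        print(f"  {item.residue}.{item.atom}: {item.reason}")
else:
    print("\nevery hydrogen in every residue received a rule.")
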