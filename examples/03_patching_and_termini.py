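"""Apply residue patches and derive termini-database directives.

A PRES patch is mapped onto a base residue to mint a standalone residue;
the same machinery, run in diff mode, yields the ordered delete / replace /
add directives of a termini-database entry, which re-applied to the base
reproduce the patched topology exactly.
"""

import tempfile

from ffport.fixtures import generate_fixture_ff
from ffport.patching import apply_patch, apply_terminus_entry
from ffport.pipeline import run_conversion_from_file

with tempfile.TemporaryDirectory() as tmp:
    config_path = generate_fixture_ff(seed=1, size=10).write(tmp)
    result = run_conversion_from_file(config_path)

src = result.source
base = src.residues["ALX"]
patched = apply_patch(base, src.patches["CTE"], "ALX_CT")
print("carboxy-terminus patch applied to the alanine-like residue:")
print(f"  atoms: {[a.name for a in patched.atoms]}")
print(f"  total charge: {patched.total_charge:+.2f} (base was "
      f"{base.total_charge:+.2f})")

print("\ngenerated C-terminus entry:")
(entry,) = result.termini["prot"]["C"]
for d in entry.directives:
    print(f"  {d}")

redone = apply_terminus_entry(entry, base, src.params)
match = {(a.name, a.type, a.charge) for a in redone.atoms} == {
    (a.name, a.type, a.charge) for a in patched.atoms
}
print(f"\ndirectives re-applied to the base reproduce the patch: {match}")
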