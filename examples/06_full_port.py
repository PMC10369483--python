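"""Write a complete GROMACS force-field directory from CHARMM-format input.

Runs the whole pipeline — parse, merge, convert, perceive, patch, termini,
hydrogen database, fixups — and serializes the result.  Output is
deterministic: re-running on the same input produces byte-identical files.
"""

import os
import tempfile

from ffport.fixtures import generate_fixture_ff
from ffport.pipeline import run_conversion_from_file

with tempfile.TemporaryDirectory() as tmp:
    config_path = generate_fixture_ff(seed=1, size=10).write(tmp)
    result = run_conversion_from_file(config_path, outdir=tmp)

    print(f"force-field directory: {os.path.basename(result.layout.directory)}")
    for name in sorted(result.layout.files):
        size = os.path.getsize(result.layout.path(name))
        print(f"  {name:<26s} {size:6d} bytes")

    print(f"\ndummy dihedral types: "
          f"{[d.types for d in result.fixreport.dummy_dihedraltypes]}")
    print(f"replicated impropers: "
          f"{[p.declared_types for p in result.fixreport.permuted_impropertypes]}")
    print(f"warnings: {result.warnings}")
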