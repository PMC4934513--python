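"""Conformational span of a ligand: its maximum intra-molecular distance.

The same flexible compound bound to different proteins can differ by
several Å in span; the metric (and the atom pair achieving it) quantifies
that at a glance. Here the synthetic ligand is rigid, so the span is the
same in the holo structure and in the docked pose.
"""

from pathlib import Path
from tempfile import mkdtemp

import motifdock as md

workdir = Path(mkdtemp())
fixture = md.make_binding_fixture(md.FixtureSpec(seed=4))
(workdir / "holo.pdb").write_text(fixture.holo_pdb)
holo = md.parse_structure(workdir / "holo.pdb")
ligand = md.select_ligand(holo, "LIG")

span, (a, b) = md.max_intraligand_distance(ligand)
print(f"ligand {ligand.het_code}: span {span:.3f} Å between {a} and {b}")

contacts = md.contact_table(holo, ligand, n=10, mode="reporting")
print("\ntop contacts (reporting mode allows carbon partners):")
for c in contacts:
    print("  ", c.label)
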