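"""Extract a ligand-binding motif from a holoenzyme.

Builds a synthetic holo structure (protein shell around a small polar
ligand), pulls out the five closest polar contacts under the expanding-radius
rule, and enumerates the four-atom sub-motifs used for querying targets.
"""

from pathlib import Path
from tempfile import mkdtemp

import motifdock as md

workdir = Path(mkdtemp())
fixture = md.make_binding_fixture(md.FixtureSpec(seed=1))
(workdir / "holo.pdb").write_text(fixture.holo_pdb)

holo = md.parse_structure(workdir / "holo.pdb")
ligand = md.select_ligand(holo, "LIG")

contacts = md.get_motif(holo, ligand, n=5)
print("closest polar contacts (residue/atom/ligand-atom/distance):")
for c in contacts:
    print("  ", c.label)

submotifs = md.enumerate_submotifs(contacts, 4)
print(f"\n{len(submotifs)} four-atom sub-motifs from the 5 contacts "
      "(each one can query a target on its own)")

motif = md.assign_groups(submotifs[0])
print("first sub-motif positions and allowed residue types:")
for atom, group in zip(motif.atoms, motif.groups):
    print(f"   {atom.key} ({atom.residue_name}) -> {sorted(group)}")
# The distances define spatial congruence; the groups let stereochemically
# equivalent residues (e.g. Asp for Glu) satisfy a position in a target.
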