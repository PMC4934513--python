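import numpy as np
import pytest

from motifdock import Atom, LigandInstance, Structure


def make_atom(name="OG", element="O", residue_name="SER", residue_seq=1,
              chain_id="A", coords=(0.0, 0.0, 0.0), serial=1, is_hetero=False,
              alt_loc="", insertion_code="", occupancy=1.0):
    return Atom(serial=serial, name=name, element=element,
                residue_name=residue_name, residue_seq=residue_seq,
                insertion_code=insertion_code, chain_id=chain_id,
                alt_loc=alt_loc, coords=np.asarray(coords, dtype=float),
                occupancy=occupancy, b_factor=20.0, is_hetero=is_hetero)


def make_structure(atom_specs, ligand_specs=(), sid="TEST"):
    """atom_specs: (name, element, resname, resseq, coords) protein atoms;
    ligand_specs: (het, resseq, [(name, element, coords), ...])."""
    atoms = [make_atom(name=n, element=e, residue_name=rn, residue_seq=rs,
                       coords=c, serial=i + 1)
             for i, (n, e, rn, rs, c) in enumerate(atom_specs)]
    ligands = []
    for het, resseq, lig_atoms in ligand_specs:
        ligands.append(LigandInstance(
            het_code=het, chain_id="A", residue_seq=resseq,
            atoms=[make_atom(name=n, element=e, residue_name=het,
                             residue_seq=resseq, coords=c, serial=100 + i,
                             is_hetero=True)
                   for i, (n, e, c) in enumerate(lig_atoms)]))
    return Structure(id=sid, atoms=atoms, ligands=ligands)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
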