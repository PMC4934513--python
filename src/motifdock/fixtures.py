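"""Synthetic binding-site fixtures with exact ground truth.

Every module in this package is testable without downloading any structure:
this module builds small holo/apo/target PDB files around a synthetic ligand
whose contact geometry is known by construction. Residues are simplified
rigid templates (plausible atom names and elements, not real rotamers)
arranged so that a designated polar atom of each binding residue is the
closest protein atom to a designated polar ligand atom, at a designed
distance; filler residues sit on an outer shell well beyond contact range.

The target is a rigidly moved copy of the holo protein (optionally with
residue substitutions inside the default stereochemical groups, e.g.
Glu→Asp). By default the rigid motion is an axis-aligned 90-degree rotation
plus a millivoxel-exact translation, so that coordinates survive the PDB
format's 3-decimal precision exactly and docking can be checked against
ground truth at 1e-6 Å through a full file round-trip.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Sequence

import numpy as np

from .docking_geometry import RigidTransform
from .structure_io import Atom, LigandInstance, Structure, structure_to_pdb

# Rigid side-chain-first residue templates: (atom name, element, offsets)
# expressed in a local frame (u = axis pointing away from the ligand,
# p/q = perpendicular). The first atom is the designated contact atom.
RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, float, float, float]]] = {
    "SER": [("OG", "O", 0.0, 0.0, 0.0), ("CB", "C", 1.4, 0.3, 0.0),
            ("CA", "C", 2.8, -0.2, 0.4), ("N", "N", 3.6, 1.0, 0.3),
            ("C", "C", 3.5, -1.2, 0.6), ("O", "O", 4.6, -1.5, 0.7)],
    "THR": [("OG1", "O", 0.0, 0.0, 0.0), ("CB", "C", 1.4, 0.0, 0.0),
            ("CG2", "C", 2.0, 1.3, 0.0), ("CA", "C", 2.8, -0.5, 0.4),
            ("N", "N", 3.6, 0.5, 0.7), ("C", "C", 3.7, -1.6, 0.4),
            ("O", "O", 4.8, -1.7, 0.5)],
    "ASP": [("OD1", "O", 0.0, 0.0, 0.0), ("CG", "C", 1.3, 0.0, 0.0),
            ("OD2", "O", 1.9, 1.1, 0.0), ("CB", "C", 2.3, -0.9, 0.3),
            ("CA", "C", 3.7, -0.7, 0.5), ("N", "N", 4.4, 0.4, 0.9),
            ("C", "C", 4.5, -1.8, 0.4), ("O", "O", 5.6, -1.9, 0.6)],
    "GLU": [("OE1", "O", 0.0, 0.0, 0.0), ("CD", "C", 1.3, 0.0, 0.0),
            ("OE2", "O", 1.9, 1.1, 0.0), ("CG", "C", 2.3, -0.9, 0.3),
            ("CB", "C", 3.7, -0.8, 0.4), ("CA", "C", 5.0, -0.5, 0.6),
            ("N", "N", 5.7, 0.6, 0.9), ("C", "C", 5.8, -1.6, 0.5),
            ("O", "O", 6.9, -1.7, 0.7)],
    "ASN": [("OD1", "O", 0.0, 0.0, 0.0), ("CG", "C", 1.3, 0.0, 0.0),
            ("ND2", "N", 1.9, 1.1, 0.0), ("CB", "C", 2.3, -0.9, 0.3),
            ("CA", "C", 3.7, -0.7, 0.5), ("N", "N", 4.4, 0.4, 0.8),
            ("C", "C", 4.5, -1.8, 0.4), ("O", "O", 5.6, -1.9, 0.6)],
    "GLN": [("OE1", "O", 0.0, 0.0, 0.0), ("CD", "C", 1.3, 0.0, 0.0),
            ("NE2", "N", 1.9, 1.1, 0.0), ("CG", "C", 2.3, -0.9, 0.3),
            ("CB", "C", 3.7, -0.8, 0.4), ("CA", "C", 5.0, -0.5, 0.6),
            ("N", "N", 5.7, 0.6, 0.9), ("C", "C", 5.8, -1.6, 0.5),
            ("O", "O", 6.9, -1.7, 0.7)],
    "LYS": [("NZ", "N", 0.0, 0.0, 0.0), ("CE", "C", 1.5, 0.0, 0.0),
            ("CD", "C", 2.6, 1.0, 0.0), ("CG", "C", 4.0, 0.9, 0.3),
            ("CB", "C", 5.1, 1.8, 0.4), ("CA", "C", 6.5, 1.6, 0.6),
            ("N", "N", 7.2, 2.6, 0.8), ("C", "C", 7.3, 0.5, 0.5),
            ("O", "O", 8.4, 0.4, 0.6)],
    "ARG": [("NH1", "N", 0.0, 0.0, 0.0), ("CZ", "C", 1.3, 0.0, 0.0),
            ("NH2", "N", 1.9, 1.1, 0.0), ("NE", "N", 2.3, -0.9, 0.2),
            ("CD", "C", 3.7, -0.8, 0.3), ("CG", "C", 4.8, 0.1, 0.5),
            ("CB", "C", 6.2, 0.0, 0.6), ("CA", "C", 7.3, 0.9, 0.7),
            ("N", "N", 8.0, 1.9, 0.8), ("C", "C", 8.2, -0.2, 0.5),
            ("O", "O", 9.3, -0.3, 0.6)],
    "TYR": [("OH", "O", 0.0, 0.0, 0.0), ("CZ", "C", 1.4, 0.0, 0.0),
            ("CE1", "C", 2.1, 1.2, 0.0), ("CE2", "C", 2.1, -1.2, 0.0),
            ("CG", "C", 3.9, 0.0, 0.2), ("CB", "C", 5.4, 0.0, 0.4),
            ("CA", "C", 6.8, 0.3, 0.5), ("N", "N", 7.5, 1.3, 0.7),
            ("C", "C", 7.7, -0.8, 0.4), ("O", "O", 8.8, -0.9, 0.5)],
    "TRP": [("NE1", "N", 0.0, 0.0, 0.0), ("CD1", "C", 1.3, 0.4, 0.0),
            ("CE2", "C", 1.3, -1.0, 0.0), ("CZ2", "C", 2.2, -2.0, 0.1),
            ("CD2", "C", 2.6, -0.7, 0.1), ("CG", "C", 2.5, 0.7, 0.1),
            ("CB", "C", 3.9, 1.0, 0.3), ("CA", "C", 5.2, 0.8, 0.5),
            ("N", "N", 5.9, 1.8, 0.7), ("C", "C", 6.1, -0.3, 0.4),
            ("O", "O", 7.2, -0.4, 0.5)],
    "HIS": [("NE2", "N", 0.0, 0.0, 0.0), ("CE1", "C", 1.3, 0.6, 0.0),
            ("CD2", "C", 1.3, -0.8, 0.0), ("CG", "C", 2.5, -0.5, 0.1),
            ("ND1", "N", 2.4, 0.8, 0.1), ("CB", "C", 3.9, -0.7, 0.3),
            ("CA", "C", 5.2, -0.4, 0.5), ("N", "N", 5.9, 0.6, 0.7),
            ("C", "C", 6.1, -1.5, 0.4), ("O", "O", 7.2, -1.6, 0.5)],
    "ALA": [("CB", "C", 0.0, 0.0, 0.0), ("CA", "C", 1.5, 0.0, 0.0),
            ("N", "N", 2.2, 1.0, 0.3), ("C", "C", 2.4, -1.1, 0.2),
            ("O", "O", 3.5, -1.2, 0.3)],
    "GLY": [("CA", "C", 0.0, 0.0, 0.0), ("N", "N", 0.7, 1.2, 0.2),
            ("C", "C", 0.9, -1.3, 0.2), ("O", "O", 2.0, -1.4, 0.3)],
    "PHE": [("CZ", "C", 0.0, 0.0, 0.0), ("CE1", "C", 0.7, 1.2, 0.0),
            ("CE2", "C", 0.7, -1.2, 0.0), ("CG", "C", 2.1, 0.0, 0.2),
            ("CB", "C", 3.6, 0.0, 0.4), ("CA", "C", 5.0, 0.3, 0.5),
            ("N", "N", 5.7, 1.3, 0.7), ("C", "C", 5.9, -0.8, 0.4),
            ("O", "O", 7.0, -0.9, 0.5)],
}

# Default synthetic ligand: one rigid small molecule with five polar atoms.
DEFAULT_LIGAND_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (0.0, 0.0, 0.0)),
    ("N1", "N", (1.4, 0.2, 0.0)),
    ("O1", "O", (-0.6, 1.2, 0.3)),
    ("C2", "C", (-0.8, -1.1, 0.2)),
    ("O2", "O", (-2.0, -1.3, 0.5)),
    ("N2", "N", (1.9, -1.0, -0.4)),
    ("C3", "C", (0.5, 0.3, 1.3)),
    ("O3", "O", (0.9, 1.4, -1.0)),
]

# Which polar ligand atom each binding residue contacts, in design order.
DEFAULT_CONTACT_PLAN: list[str] = ["N1", "O1", "O2", "N2", "O3"]
DEFAULT_BINDING_TYPES: list[str] = ["SER", "ASP", "GLU", "LYS", "ASN"]
FILLER_TYPES: list[str] = ["ALA", "GLY", "PHE", "TYR", "THR", "HIS", "GLN", "ARG"]

# Residue substitutions consistent with the default group scheme keep the
# contact-atom element (O or N) unchanged.
_SUBSTITUTABLE = {("GLU", "ASP"), ("ASP", "GLU"), ("ASN", "GLN"), ("GLN", "ASN"),
                  ("SER", "THR"), ("THR", "SER"), ("LYS", "ARG"), ("ARG", "LYS"),
                  ("TYR", "TRP")}

# The 24 proper axis-aligned rotations: exact on 3-decimal coordinates.
def _axis_rotations() -> list[np.ndarray]:
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    return mats


_LATTICE_ROTATIONS = _axis_rotations()


@dataclasses.dataclass
class FixtureSpec:
    """Recipe for one synthetic binding fixture (same seed → same bytes)."""

    seed: int = 0
    n_residues: int = 20
    binding_types: Sequence[str] = tuple(DEFAULT_BINDING_TYPES)
    contact_distances: Sequence[float] | None = None   # Å; default 2.6..3.4
    placement: str = "shell"
    transform: RigidTransform | None = None            # None → seeded lattice motion
    substitutions: dict[str, str] | None = None        # applied to the target only
    ligand_template: Sequence[tuple[str, str, tuple[float, float, float]]] = \
        tuple(DEFAULT_LIGAND_TEMPLATE)
    het_code: str = "LIG"


@dataclasses.dataclass
class FixtureResult:
    holo_pdb: str
    apo_pdb: str
    target_pdb: str
    ground_truth: dict

    @property
    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, indent=1)


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, helper)
    p /= np.linalg.norm(p)
    return p, np.cross(u, p)


def _instantiate_residue(res_type: str, contact_pos: np.ndarray, axis: np.ndarray,
                         chain: str, resseq: int, serial0: int) -> list[Atom]:
    p, q = _orthonormal_basis(axis)
    atoms = []
    for i, (name, element, a, b, c) in enumerate(RESIDUE_TEMPLATES[res_type]):
        pos = contact_pos + a * axis + b * p + c * q
        atoms.append(Atom(serial=serial0 + i, name=name, element=element,
                          residue_name=res_type, residue_seq=resseq,
                          insertion_code="", chain_id=chain, alt_loc="",
                          coords=pos, occupancy=1.0, b_factor=20.0))
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _round3(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float), 3)


def make_binding_fixture(spec: FixtureSpec) -> FixtureResult:
    """Build holo/apo/target PDB texts plus an exact ground-truth record.

    The ground truth holds the applied rigid motion, the true contact motif
    (atom keys, contact distances in design order) and the true docked
    ligand coordinates in the target frame.
    """
    binding_types = list(spec.binding_types)
    if spec.n_residues < len(binding_types) or not binding_types:
        raise ValueError(
            f"n_residues must be >= {max(len(binding_types), 1)}, got {spec.n_residues}")
    for t in binding_types:
        if t not in RESIDUE_TEMPLATES:
            raise ValueError(f"unknown residue type {t!r}")
    rng = np.random.default_rng(spec.seed)
    global_rot = _random_rotation(rng)

    distances = list(spec.contact_distances) if spec.contact_distances is not None \
        else [2.6 + 0.2 * i for i in range(len(binding_types))]
    if len(distances) != len(binding_types):
        raise ValueError("contact_distances must match binding_types in length")

    lig_names = [n for n, _, _ in spec.ligand_template]
    lig_coords = np.array([c for _, _, c in spec.ligand_template])
    centroid = lig_coords.mean(axis=0)
    plan = DEFAULT_CONTACT_PLAN[:len(binding_types)]
    if len(plan) < len(binding_types):
        raise ValueError("not enough polar ligand atoms for the binding residues")

    chain = "A"
    protein_atoms: list[Atom] = []
    serial = 1
    contact_info = []
    for i, (res_type, lig_atom_name, d) in enumerate(zip(binding_types, plan, distances)):
        li = lig_names.index(lig_atom_name)
        u = lig_coords[li] - centroid
        u = u / np.linalg.norm(u)
        contact_pos = lig_coords[li] + d * u
        resseq = 10 * (i + 1)
        atoms = _instantiate_residue(res_type, contact_pos, u, chain, resseq, serial)
        serial += len(atoms)
        protein_atoms.extend(atoms)
        contact_info.append({"residue": f"{chain}:{resseq}",
                             "atom": atoms[0].name, "residue_name": res_type,
                             "ligand_atom": lig_atom_name, "distance": d})

    n_fillers = spec.n_residues - len(binding_types)
    for j in range(n_fillers):
        res_type = FILLER_TYPES[int(rng.integers(len(FILLER_TYPES)))]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        radius = float(rng.uniform(8.5, 13.0))
        contact_pos = centroid + radius * u
        resseq = 100 + j
        atoms = _instantiate_residue(res_type, contact_pos, u, chain, resseq, serial)
        serial += len(atoms)
        protein_atoms.extend(atoms)

    # one seeded global rotation for variety, then snap to PDB precision
    def finalize(atoms_coords: np.ndarray) -> np.ndarray:
        return _round3((atoms_coords - centroid) @ global_rot.T)

    protein_atoms = [a.moved_to(finalize(a.coords)) for a in protein_atoms]
    lig_final = finalize(lig_coords)
    ligand_atoms = [Atom(serial=serial + i, name=n, element=e,
                         residue_name=spec.het_code, residue_seq=900,
                         insertion_code="", chain_id=chain, alt_loc="",
                         coords=c, occupancy=1.0, b_factor=20.0, is_hetero=True)
                    for i, ((n, e, _), c) in enumerate(zip(spec.ligand_template, lig_final))]
    ligand = LigandInstance(het_code=spec.het_code, chain_id=chain,
                            residue_seq=900, atoms=ligand_atoms)

    holo = Structure(id=f"HOLO{spec.seed}", atoms=protein_atoms, ligands=[ligand])
    apo = Structure(id=f"APO{spec.seed}", atoms=list(protein_atoms), ligands=[])

    if spec.transform is not None:
        motion = spec.transform
    else:
        rot = _LATTICE_ROTATIONS[int(rng.integers(len(_LATTICE_ROTATIONS)))]
        shift = _round3(rng.uniform(-20.0, 20.0, size=3))
        motion = RigidTransform(rotation=rot, translation=shift)

    subs = dict(spec.substitutions or {})
    for old, new in subs.items():
        if (old, new) not in _SUBSTITUTABLE:
            raise ValueError(f"unsupported substitution {old}->{new}")

    target_atoms: list[Atom] = []
    by_residue: dict[tuple, list[Atom]] = {}
    for a in protein_atoms:
        by_residue.setdefault((a.chain_id, a.residue_seq), []).append(a)
    serial_t = 1
    for (ch, resseq), atoms in by_residue.items():
        res_type = atoms[0].residue_name
        if res_type in subs:
            # rebuild with the substituted template at the moved contact atom,
            # preserving the residue's axis, so the motif geometry is intact
            new_type = subs[res_type]
            contact_pos = motion.apply(atoms[0].coords)
            axis_vec = motion.rotation @ (atoms[1].coords - atoms[0].coords)
            axis_vec /= np.linalg.norm(axis_vec)
            new_atoms = _instantiate_residue(new_type, contact_pos, axis_vec,
                                             ch, resseq, serial_t)
            new_atoms = [a2.moved_to(_round3(a2.coords)) for a2 in new_atoms]
        else:
            new_atoms = []
            for a2 in atoms:
                new_atoms.append(dataclasses.replace(
                    a2, serial=serial_t + len(new_atoms),
                    coords=_round3(motion.apply(a2.coords))))
        serial_t += len(new_atoms)
        target_atoms.extend(new_atoms)
    target = Structure(id=f"TARG{spec.seed}", atoms=target_atoms, ligands=[])

    docked_truth = _round3(motion.apply(np.array([a.coords for a in ligand_atoms])))
    # actual contact distances after rounding, for the ground-truth record
    measured = []
    for info in contact_info:
        resseq = int(info["residue"].split(":")[1])
        pa = holo.find_atom(chain, resseq, info["atom"])
        la = ligand_atoms[lig_names.index(info["ligand_atom"])]
        measured.append(float(np.linalg.norm(pa.coords - la.coords)))

    ground_truth = {
        "seed": spec.seed,
        "transform": {"rotation": motion.rotation.tolist(),
                      "translation": motion.translation.tolist()},
        "motif": [dict(info, measured_distance=round(m, 6))
                  for info, m in zip(contact_info, measured)],
        "docked_ligand_coords": docked_truth.tolist(),
        "ligand_atom_names": lig_names,
        "substitutions": subs,
        "het_code": spec.het_code,
    }
    return FixtureResult(holo_pdb=structure_to_pdb(holo),
                         apo_pdb=structure_to_pdb(apo),
                         target_pdb=structure_to_pdb(target),
                         ground_truth=ground_truth)


@dataclasses.dataclass
class PotentialFixture:
    table: dict[str, float]       # atom.key -> potential, kT/e
    rule: str
    parameters: dict

    def to_tsv(self, structure: Structure) -> str:
        lines = ["# chain\tresseq\tresname\tatomname\tpotential_kT_e"]
        for a in structure.atoms:
            lines.append(f"{a.chain_id}\t{a.residue_seq}\t{a.residue_name}\t"
                         f"{a.name}\t{self.table[a.key]:.6g}")
        return "\n".join(lines) + "\n"


def make_potential_fixture(structure: Structure, rule: str = "constant",
                           value: float = 1.0, axis: int = 0, slope: float = 1.0,
                           charge_pos: np.ndarray | None = None,
                           charge: float = 1.0, kappa: float = 0.1,
                           eps_r: float = 10.0) -> PotentialFixture:
    """Per-atom potentials with closed-form ground truth.

    ``constant``: every atom gets ``value`` (all PDs are 0). ``ramp``:
    potential = slope x coordinate along ``axis`` (PD between two atoms is
    slope times their coordinate difference). ``charges``: screened Coulomb
    of a single point charge, monotone in inverse distance.
    """
    table: dict[str, float] = {}
    if rule == "constant":
        params = {"value": value}
        for a in structure.atoms:
            table[a.key] = value
    elif rule == "ramp":
        params = {"axis": axis, "slope": slope}
        for a in structure.atoms:
            table[a.key] = slope * float(a.coords[axis])
    elif rule == "charges":
        pos = np.zeros(3) if charge_pos is None else np.asarray(charge_pos, dtype=float)
        params = {"charge_pos": pos.tolist(), "charge": charge,
                  "kappa": kappa, "eps_r": eps_r}
        for a in structure.atoms:
            r = float(np.linalg.norm(a.coords - pos))
            table[a.key] = charge * np.exp(-kappa * r) / (eps_r * r) if r > 1e-9 else 0.0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return PotentialFixture(table=table, rule=rule, parameters=params)
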