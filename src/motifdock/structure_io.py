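"""Read and write macromolecular structures and docking outputs.

Structures are held as flat, ordered collections of :class:`Atom` records in
the coordinate frame of the source file (Å, author residue numbering).
Parsing is delegated to gemmi; writing uses fixed-column PDB formatting so
that headers and chain relabeling of docked poses are fully controlled.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(Exception):
    """Base class for structure I/O errors."""


class ParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class LigandNotFoundError(StructureError):
    pass


class AmbiguousLigandError(StructureError):
    pass


class AtomLookupError(StructureError):
    pass


@dataclasses.dataclass(frozen=True, eq=False)
class Atom:
    """A single heavy atom with PDB identity and Cartesian coordinates (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    alt_loc: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)

    @property
    def residue_id(self) -> str:
        """Residue identity string, e.g. ``A:205`` or ``A:52A`` with icode."""
        return f"{self.chain_id}:{self.residue_seq}{self.insertion_code.strip()}"

    @property
    def key(self) -> str:
        """Unique atom identity within a model, e.g. ``A:630:OG``."""
        return f"{self.residue_id}:{self.name}"

    @property
    def label(self) -> str:
        """Human-readable label in the field's style, e.g. ``S630/OG``."""
        one = THREE_TO_ONE.get(self.residue_name, self.residue_name)
        return f"{one}{self.residue_seq}{self.insertion_code.strip()}/{self.name}"

    def moved_to(self, coords: np.ndarray) -> "Atom":
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclasses.dataclass
class LigandInstance:
    """One hetero group (ligand copy) in a structure."""

    het_code: str
    chain_id: str
    residue_seq: int
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("LigandInstance requires at least one atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def moved_to(self, coords: np.ndarray) -> "LigandInstance":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return LigandInstance(self.het_code, self.chain_id, self.residue_seq, atoms)


@dataclasses.dataclass
class Structure:
    """A parsed model: ordered protein atoms plus ligand groups."""

    id: str
    atoms: list[Atom]
    ligands: list[LigandInstance]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)

    def select_chain(self, chain_id: str) -> "Structure":
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        ligands = [l for l in self.ligands if l.chain_id == chain_id]
        return Structure(id=f"{self.id}{chain_id}", atoms=atoms, ligands=ligands)

    def find_atom(self, chain_id: str, residue_seq: int, name: str,
                  insertion_code: str = "") -> Atom:
        for a in self.atoms:
            if (a.chain_id == chain_id and a.residue_seq == residue_seq
                    and a.name == name
                    and a.insertion_code.strip() == insertion_code.strip()):
                return a
        raise AtomLookupError(
            f"atom {chain_id}:{residue_seq}{insertion_code}:{name} not found in {self.id}")


def _apply_altloc_policy(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom identity: highest occupancy, then
    alt-loc letter order. Preserves file order of the survivors."""
    best: dict[tuple, tuple[int, Atom]] = {}
    for idx, atom in enumerate(atoms):
        ident = (atom.chain_id, atom.residue_seq, atom.insertion_code,
                 atom.residue_name, atom.name)
        if ident not in best:
            best[ident] = (idx, atom)
            continue
        _, incumbent = best[ident]
        if (atom.occupancy, _altloc_rank(atom.alt_loc)) > (
                incumbent.occupancy, _altloc_rank(incumbent.alt_loc)):
            best[ident] = (best[ident][0], atom)
    return [a for _, a in sorted(best.values(), key=lambda pair: pair[0])]


def _altloc_rank(alt_loc: str) -> int:
    # Earlier letters win ties, so rank them higher.
    if not alt_loc.strip():
        return 0
    return -ord(alt_loc)


def parse_structure(path: str | Path, chain_filter: str | None = None,
                    model_index: int = 0, keep_waters: bool = False,
                    keep_hydrogens: bool = False) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Waters and hydrogens are dropped by default; one conformer is kept per
    alt-loc group (highest occupancy, ties to the earlier letter); model 1
    is read unless ``model_index`` says otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if model_index >= len(st):
        raise ParseError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    protein: list[Atom] = []
    hetero: list[Atom] = []
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for residue in chain:
            if residue.name in WATER_NAMES and not keep_waters:
                continue
            is_het = residue.het_flag == "H"
            for atom in residue:
                element = atom.element.name.upper()
                if element in ("H", "D") and not keep_hydrogens:
                    continue
                altloc = atom.altloc if atom.altloc not in ("\0", None) else ""
                rec = Atom(
                    serial=atom.serial,
                    name=atom.name,
                    element=element,
                    residue_name=residue.name,
                    residue_seq=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    chain_id=chain.name,
                    alt_loc=altloc.strip(),
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                    is_hetero=is_het,
                )
                (hetero if is_het else protein).append(rec)

    protein = _apply_altloc_policy(protein)
    hetero = _apply_altloc_policy(hetero)
    if not protein and not hetero:
        raise EmptyStructureError(
            f"{path}: selection (chain={chain_filter!r}) contains no atoms")

    ligands = _group_ligands(hetero)
    sid = path.stem.upper() + (chain_filter or "")
    return Structure(id=sid, atoms=protein, ligands=ligands)


def _group_ligands(hetero: Iterable[Atom]) -> list[LigandInstance]:
    groups: dict[tuple, list[Atom]] = {}
    for atom in hetero:
        groups.setdefault(
            (atom.residue_name, atom.chain_id, atom.residue_seq, atom.insertion_code),
            []).append(atom)
    return [LigandInstance(het_code=k[0], chain_id=k[1], residue_seq=k[2], atoms=v)
            for k, v in groups.items()]


def select_ligand(s: Structure, het_code: str, chain: str | None = None,
                  residue_seq: int | None = None) -> LigandInstance:
    """Return the unique ligand copy matching ``het_code`` (and optional
    chain / residue number); ambiguity is an error, not a guess."""
    matches = [l for l in s.ligands if l.het_code == het_code]
    if chain is not None:
        matches = [l for l in matches if l.chain_id == chain]
    if residue_seq is not None:
        matches = [l for l in matches if l.residue_seq == residue_seq]
    if not matches:
        raise LigandNotFoundError(
            f"no ligand {het_code!r} (chain={chain}, seq={residue_seq}) in {s.id}; "
            f"present: {sorted({l.het_code for l in s.ligands})}")
    if len(matches) > 1:
        listing = ", ".join(f"{l.het_code}/{l.chain_id}/{l.residue_seq}" for l in matches)
        raise AmbiguousLigandError(
            f"ligand {het_code!r} is ambiguous in {s.id}: {listing}; "
            "pass chain and/or residue_seq")
    return matches[0]


# ---------------------------------------------------------------------------
# Writing


def _format_atom_line(atom: Atom, serial: int, record: str, chain_id: str | None = None) -> str:
    name = atom.name
    # PDB column rule: 1-3 character names with 1-letter elements start in
    # column 14; 4-character names (or 2-letter elements) use column 13.
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4}{(atom.alt_loc or ' ')[:1]}"
        f"{atom.residue_name:>3} {(chain_id or atom.chain_id)[:1]}"
        f"{atom.residue_seq:>4}{(atom.insertion_code or ' ')[:1]}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2}"
    )


def structure_to_pdb(s: Structure, header_lines: Sequence[str] = ()) -> str:
    """Render a structure as PDB text (protein atoms, TER, then ligands)."""
    lines = [f"REMARK   3 {h}" for h in header_lines]
    serial = 0
    for atom in s.atoms:
        serial += 1
        lines.append(_format_atom_line(atom, serial, "ATOM"))
    if s.atoms:
        lines.append(f"TER   {serial + 1:>5}")
        serial += 1
    for lig in s.ligands:
        for atom in lig.atoms:
            serial += 1
            lines.append(_format_atom_line(atom, serial, "HETATM"))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(s: Structure, path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    Path(path).write_text(structure_to_pdb(s, header_lines))


def write_docked(pose, target: Structure, out_pdb: str | Path,
                 out_pml: str | Path, ligand_chain: str = "Z",
                 header_lines: Sequence[str] = ()) -> None:
    """Write a docked pose: a PDB with the transplanted ligand on its own
    chain, and a PyMOL command script highlighting motif residues + ligand.

    ``pose`` is a :class:`motifdock.docking_geometry.DockedPose` whose ligand
    coordinates share a frame with ``target``.
    """
    out_pdb, out_pml = Path(out_pdb), Path(out_pml)

    used = {a.chain_id for a in target.atoms}
    if ligand_chain in used:
        for candidate in "ZYXWVU0123456789":
            if candidate not in used:
                ligand_chain = candidate
                break

    lines = [f"REMARK   3 {h}" for h in header_lines]
    serial = 0
    for atom in target.atoms:
        serial += 1
        lines.append(_format_atom_line(atom, serial, "ATOM"))
    lines.append(f"TER   {serial + 1:>5}")
    serial += 1
    for atom in pose.ligand_atoms:
        serial += 1
        lines.append(_format_atom_line(atom, serial, "HETATM", chain_id=ligand_chain))
    lines.append("END")
    try:
        out_pdb.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise StructureError(f"cannot write {out_pdb}: {exc}") from exc

    anchor_sel = " or ".join(
        f"(chain {a.chain_id} and resi {a.residue_seq})" for a in pose.anchors_target)
    pml = [
        f"load {out_pdb.name}, docked",
        f"select motif_residues, docked and ({anchor_sel})" if anchor_sel else
        "select motif_residues, none",
        f"select ligand, docked and chain {ligand_chain} and hetatm",
        "hide everything, docked",
        "show cartoon, docked",
        "show sticks, motif_residues",
        "show sticks, ligand",
        "color yellow, motif_residues",
        "color magenta, ligand",
        "zoom ligand, 8",
    ]
    try:
        out_pml.write_text("\n".join(pml) + "\n")
    except OSError as exc:
        raise StructureError(f"cannot write {out_pml}: {exc}") from exc
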