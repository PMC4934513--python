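"""Ligand-contact motif extraction from a holoenzyme.

The binding motif of a ligand is defined by the protein atoms closest to it
that can form polar (non-hydrophobic) interactions. Candidates are gathered
under an expanding-radius schedule: starting at 2.5 Å and growing in 0.1 Å
increments, protein atoms within the radius of any ligand atom are accepted
if the (ligand element, protein element) pair is on the polar whitelist, at
most one atom per protein residue (the closest), until n atoms are found or
the radius cap is reached. Sub-motifs of size k are then enumerated as all
C(n, k) combinations, preserving ascending-distance order.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .electrostatics import PotentialAssignment, pairwise_pd
from .structure_io import Atom, LigandInstance, Structure

# Accepted (ligand element, protein element) pairs: polar contacts only.
# Carbon is excluded entirely; sulfur pairs only with hydrogen, so after
# hydrogen-stripping S effectively drops out of strict extraction.
ACCEPTED_ATOM_PAIRS: frozenset[tuple[str, str]] = frozenset({
    ("O", "N"), ("N", "O"), ("O", "H"), ("H", "O"), ("O", "O"),
    ("N", "N"), ("N", "H"), ("H", "N"), ("S", "H"), ("H", "S"),
})

START_RADIUS = 2.5   # Å
RADIUS_STEP = 0.1    # Å
RADIUS_CAP = 8.0     # Å; beyond this, "contacts" are not binding interactions

# Stereochemically equivalent residue sets for motif positions. Any residue
# type not listed matches only itself.
GROUP_SCHEMES: dict[str, tuple[frozenset[str], ...]] = {
    "default": (
        frozenset({"ASP", "GLU"}),
        frozenset({"ASN", "GLN"}),
        frozenset({"SER", "THR"}),
        frozenset({"LYS", "ARG"}),
        frozenset({"TYR", "TRP", "PHE"}),
        frozenset({"HIS"}),
        frozenset({"CYS"}),
        frozenset({"GLY", "ALA"}),
    ),
    "identity": (),
}


class MotifError(Exception):
    pass


class InsufficientContactsError(MotifError):
    def __init__(self, needed: int, found: int, radius: float):
        self.needed, self.found, self.radius = needed, found, radius
        super().__init__(
            f"only {found} qualifying contact(s) within {radius:.1f} Å, needed {needed}")


@dataclasses.dataclass(frozen=True)
class ContactRecord:
    """One protein-ligand contact, in the field's R/A/LA/D style."""

    protein_atom: Atom
    ligand_atom: Atom
    distance: float

    @property
    def label(self) -> str:
        return (f"{self.protein_atom.label}/"
                f"{self.ligand_atom.name}/{self.distance:.1f}")


@dataclasses.dataclass(frozen=True, eq=False)
class Motif:
    """An ordered tuple of protein atoms with pairwise feature matrices."""

    atoms: tuple[Atom, ...]
    distances: np.ndarray                      # k x k, Å
    pds: np.ndarray | None = None              # k x k, kT/e
    groups: tuple[frozenset[str], ...] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        k = len(self.atoms)
        if k < 3:
            raise MotifError("a motif needs at least 3 atoms")
        if len({a.residue_id for a in self.atoms}) != k:
            raise MotifError("motif atoms must come from distinct residues")
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (k, k) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise MotifError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "distances", d)

    @property
    def k(self) -> int:
        return len(self.atoms)

    @property
    def residue_types(self) -> tuple[str, ...]:
        return tuple(a.residue_name for a in self.atoms)

    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "source_id": self.source_id,
            "atoms": [{"key": a.key, "residue_name": a.residue_name,
                       "name": a.name, "element": a.element,
                       "coords": [round(float(c), 6) for c in a.coords]}
                      for a in self.atoms],
            "groups": [sorted(g) for g in self.groups] if self.groups else None,
            "distances": np.round(self.distances, 6).tolist(),
            "pds": np.round(self.pds, 6).tolist() if self.pds is not None else None,
        }
        return json.dumps(payload, indent=1)


def motif_from_json(text: str) -> Motif:
    """Inverse of :meth:`Motif.to_json` (atoms are reconstructed records)."""
    payload = json.loads(text)
    atoms = []
    for i, rec in enumerate(payload["atoms"]):
        chain, resseq, name = rec["key"].split(":")
        seq = int("".join(ch for ch in resseq if ch.isdigit() or ch == "-"))
        icode = "".join(ch for ch in resseq if ch.isalpha())
        atoms.append(Atom(serial=i + 1, name=name, element=rec["element"],
                          residue_name=rec["residue_name"], residue_seq=seq,
                          insertion_code=icode, chain_id=chain, alt_loc="",
                          coords=np.array(rec["coords"], dtype=float)))
    groups = tuple(frozenset(g) for g in payload["groups"]) \
        if payload.get("groups") else None
    pds = np.array(payload["pds"], dtype=float) if payload.get("pds") is not None else None
    return Motif(atoms=tuple(atoms), distances=np.array(payload["distances"], dtype=float),
                 pds=pds, groups=groups, source_id=payload.get("source_id", ""))


def motif_from_atoms(atoms: Sequence[Atom],
                     potentials: PotentialAssignment | None = None,
                     source_id: str = "") -> Motif:
    """Build a motif from atoms in their given order, filling matrices."""
    coords = np.array([a.coords for a in atoms])
    distances = cdist(coords, coords)
    np.fill_diagonal(distances, 0.0)
    pds = pairwise_pd(potentials, atoms) if potentials is not None else None
    return Motif(atoms=tuple(atoms), distances=distances, pds=pds,
                 source_id=source_id)


def _qualifying_pairs(protein: Structure, ligand: LigandInstance,
                      mode: str) -> list[tuple[float, Atom, Atom]]:
    pairs = []
    lig_atoms = ligand.atoms
    prot_atoms = protein.atoms
    if not prot_atoms:
        return []
    d = cdist(np.array([a.coords for a in lig_atoms]),
              np.array([a.coords for a in prot_atoms]))
    for i, la in enumerate(lig_atoms):
        for j, pa in enumerate(prot_atoms):
            if mode == "strict":
                if (la.element, pa.element) not in ACCEPTED_ATOM_PAIRS:
                    continue
            else:  # reporting: polar ligand atom, any protein partner
                if la.element not in ("N", "O", "S"):
                    continue
            pairs.append((float(d[i, j]), pa, la))
    return pairs


def get_motif(protein: Structure, ligand: LigandInstance, n: int = 5, *,
              start_radius: float = START_RADIUS, radius_step: float = RADIUS_STEP,
              radius_cap: float = RADIUS_CAP) -> list[ContactRecord]:
    """Expanding-radius extraction of the n closest polar contacts.

    Returns n contact records sorted by ascending distance, each from a
    distinct protein residue, every pair on the polar whitelist. Raises
    :class:`InsufficientContactsError` if the cap is hit first.
    """
    if n < 3:
        raise MotifError(f"n must be >= 3, got {n}")
    if not ligand.atoms:
        raise MotifError("empty ligand")
    pairs = _qualifying_pairs(protein, ligand, "strict")
    # deterministic processing order: ascending distance, then identity
    pairs.sort(key=lambda t: (t[0], t[1].chain_id, t[1].residue_seq, t[1].name))

    selected: list[ContactRecord] = []
    seen_residues: set[str] = set()
    radius = start_radius
    consumed = 0
    while radius <= radius_cap + 1e-9 and len(selected) < n:
        while consumed < len(pairs) and pairs[consumed][0] <= radius:
            dist, pa, la = pairs[consumed]
            consumed += 1
            if pa.residue_id in seen_residues:
                continue
            seen_residues.add(pa.residue_id)
            selected.append(ContactRecord(protein_atom=pa, ligand_atom=la, distance=dist))
            if len(selected) == n:
                break
        radius += radius_step
    if len(selected) < n:
        raise InsufficientContactsError(needed=n, found=len(selected), radius=radius_cap)
    return selected


def contact_table(protein: Structure, ligand: LigandInstance, n: int = 10,
                  mode: str = "strict", dedupe_residues: bool = True,
                  radius_cap: float = RADIUS_CAP) -> list[ContactRecord]:
    """The n closest contacts, for reporting.

    ``strict`` applies the polar pair whitelist of :func:`get_motif`;
    ``reporting`` accepts any protein partner (including carbon) for a polar
    (N/O/S) ligand atom, as binding-site tables in the literature do. Unlike
    :func:`get_motif`, an incomplete table is returned rather than raised on.
    """
    if mode not in ("strict", "reporting"):
        raise MotifError(f"unknown contact mode {mode!r}")
    pairs = _qualifying_pairs(protein, ligand, mode)
    pairs.sort(key=lambda t: (t[0], t[1].chain_id, t[1].residue_seq, t[1].name))
    out: list[ContactRecord] = []
    seen: set[str] = set()
    for dist, pa, la in pairs:
        if dist > radius_cap:
            break
        if dedupe_residues:
            if pa.residue_id in seen:
                continue
            seen.add(pa.residue_id)
        out.append(ContactRecord(protein_atom=pa, ligand_atom=la, distance=dist))
        if len(out) == n:
            break
    return out


def contacts_to_tsv(contacts: Sequence[ContactRecord],
                    header_lines: Sequence[str] = ()) -> str:
    lines = [f"# {h}" for h in header_lines]
    lines.append("residue\tatom\tligand_atom\tdistance_A")
    for c in contacts:
        lines.append(f"{c.protein_atom.residue_name}{c.protein_atom.residue_seq}\t"
                     f"{c.protein_atom.name}\t{c.ligand_atom.name}\t{c.distance:.1f}")
    return "\n".join(lines) + "\n"


def enumerate_submotifs(contacts: Sequence[ContactRecord], k: int,
                        potentials: PotentialAssignment | None = None,
                        source_id: str = "") -> list[Motif]:
    """All C(m, k) sub-motifs of the contact atoms, order preserved."""
    m = len(contacts)
    if not 3 <= k <= m:
        raise ValueError(f"need 3 <= k <= {m}, got k={k}")
    atoms = [c.protein_atom for c in contacts]
    return [motif_from_atoms([atoms[i] for i in combo], potentials=potentials,
                             source_id=source_id)
            for combo in itertools.combinations(range(m), k)]


def assign_groups(motif: Motif, scheme: str = "default") -> Motif:
    """Attach per-position allowed residue-type sets under a named scheme."""
    if scheme not in GROUP_SCHEMES:
        raise MotifError(
            f"unknown group scheme {scheme!r}; known: {sorted(GROUP_SCHEMES)}")
    groups = []
    for atom in motif.atoms:
        group = frozenset({atom.residue_name})
        for candidate in GROUP_SCHEMES[scheme]:
            if atom.residue_name in candidate:
                group = candidate
                break
        groups.append(group)
    return dataclasses.replace(motif, groups=tuple(groups))
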