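"""Rigid-body ligand transplantation via a canonical 3-point frame.

The canonical frame of an anchor triplet (a1, a2, a3) puts a1 at the origin,
a2 on the +Y axis and a3 in the Z=0 plane with positive X. Transforming the
holoenzyme (with its ligand) and the target protein each into the canonical
frame of their own anchor triplets places all three in one unified
coordinate system, which transplants the ligand into the target's binding
site. Only proper rotations are used, so molecular chirality is preserved.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .motif_extract import ContactRecord, contact_table
from .motif_search import superposition_rmsd
from .structure_io import Atom, LigandInstance, Structure


class GeometryError(Exception):
    pass


class DegenerateGeometryError(GeometryError):
    pass


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t with R a proper rotation (det = +1)."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("improper rotation (reflection) rejected")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(rotation=self.rotation @ other.rotation,
                              translation=self.rotation @ other.translation
                              + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def to_json(self) -> str:
        return json.dumps({"rotation": np.round(self.rotation, 12).tolist(),
                           "translation": np.round(self.translation, 12).tolist()})


def canonical_frame(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray) -> RigidTransform:
    """Transform sending a1 to the origin, a2 onto +Y, a3 into Z=0 (x > 0)."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    a3 = np.asarray(a3, dtype=float)
    y = a2 - a1
    ny = np.linalg.norm(y)
    if ny < 1e-8:
        raise DegenerateGeometryError("anchor atoms 1 and 2 coincide")
    y = y / ny
    v = a3 - a1
    x = v - (v @ y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise DegenerateGeometryError("anchor atoms are collinear")
    x = x / nx
    z = np.cross(x, y)
    rot = np.vstack([x, y, z])
    return RigidTransform(rotation=rot, translation=-rot @ a1)


def kabsch_transform(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Proper rigid transform minimizing RMSD of ``moving`` onto ``fixed``."""
    a = np.asarray(fixed, dtype=float)
    b = np.asarray(moving, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise GeometryError("need two equal sets of >= 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det((u @ vt).T))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    return RigidTransform(rotation=rot, translation=ca - rot @ cb)


@dataclasses.dataclass
class DockedPose:
    """A transplanted ligand plus the transforms and anchors that made it."""

    ligand_atoms: list[Atom]
    het_code: str
    transform_holo: RigidTransform
    transform_target: RigidTransform
    anchors_holo: tuple[Atom, ...]
    anchors_target: tuple[Atom, ...]
    frame: str                   # canonical | target
    anchor_rmsd: float           # Å, optimal superposition of anchor sets

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms])

    def as_ligand(self) -> LigandInstance:
        return LigandInstance(het_code=self.het_code,
                              chain_id=self.ligand_atoms[0].chain_id,
                              residue_seq=self.ligand_atoms[0].residue_seq,
                              atoms=list(self.ligand_atoms))


def _resolve_anchor(structure: Structure, anchor) -> Atom:
    if isinstance(anchor, Atom):
        return anchor
    if isinstance(anchor, str):
        chain, resseq, name = anchor.split(":")
        icode = "".join(ch for ch in resseq if ch.isalpha())
        seq = int("".join(ch for ch in resseq if ch.isdigit() or ch == "-"))
        return structure.find_atom(chain, seq, name, icode)
    raise GeometryError(f"cannot interpret anchor spec {anchor!r}")


def dock(holo: Structure, ligand: LigandInstance,
         holo_anchor: Sequence, target: Structure, target_anchor: Sequence,
         frame: str = "target", mode: str = "three_point") -> DockedPose:
    """Transplant ``ligand`` from the holoenzyme into the target.

    Anchors are matched position-to-position (atoms or ``chain:resseq:name``
    strings). ``three_point`` mode uses the canonical frames of the first
    three anchors; ``kabsch`` mode least-squares-fits all k >= 3 anchors.
    In the ``target`` frame the pose lands in the target's original
    coordinates; in the ``canonical`` frame both proteins and the ligand sit
    in the shared canonical frame of their anchors.
    """
    if frame not in ("target", "canonical"):
        raise GeometryError(f"unknown frame {frame!r}")
    if mode not in ("three_point", "kabsch"):
        raise GeometryError(f"unknown anchoring mode {mode!r}")
    ha = tuple(_resolve_anchor(holo, a) for a in holo_anchor)
    ta = tuple(_resolve_anchor(target, a) for a in target_anchor)
    if len(ha) != len(ta) or len(ha) < 3:
        raise GeometryError("need matched anchor lists of length >= 3")
    h_pts = np.array([a.coords for a in ha])
    t_pts = np.array([a.coords for a in ta])

    if mode == "three_point":
        t_holo = canonical_frame(*h_pts[:3])
        t_target = canonical_frame(*t_pts[:3])
    else:
        t_holo = kabsch_transform(h_pts, t_pts)   # holo coords -> target frame
        t_target = RigidTransform.identity()

    anchor_rmsd = superposition_rmsd(h_pts, t_pts)

    lig_coords = ligand.coords
    if mode == "three_point":
        canonical_coords = t_holo.apply(lig_coords)
        if frame == "canonical":
            new_coords = canonical_coords
        else:
            new_coords = t_target.inverse().apply(canonical_coords)
    else:
        new_coords = t_holo.apply(lig_coords)

    atoms = [a.moved_to(c) for a, c in zip(ligand.atoms, new_coords)]
    # kabsch mode lands directly in the target's original coordinates
    frame_out = "target" if mode == "kabsch" else frame
    return DockedPose(ligand_atoms=atoms, het_code=ligand.het_code,
                      transform_holo=t_holo, transform_target=t_target,
                      anchors_holo=ha, anchors_target=ta, frame=frame_out,
                      anchor_rmsd=anchor_rmsd)


def pose_contacts(pose: DockedPose, target: Structure,
                  n: int = 10) -> list[ContactRecord]:
    """The n closest target contacts of the posed ligand (reporting mode)."""
    if pose.frame != "target":
        raise GeometryError("pose must be in the target frame for contact analysis")
    return contact_table(target, pose.as_ligand(), n=n, mode="reporting")


@dataclasses.dataclass
class ClashReport:
    count: int
    min_distance: float          # Å; inf when the sets are disjoint beyond cutoff
    cutoff: float


def clash_report(pose: DockedPose, target: Structure,
                 cutoff: float = 2.0) -> ClashReport:
    """Count target heavy atoms within ``cutoff`` of any posed ligand atom.

    All target atoms are counted, including the anchor residues' own atoms;
    distances at or under typical H-bond lengths are flagged, not failed.
    """
    if not target.atoms:
        return ClashReport(count=0, min_distance=float("inf"), cutoff=cutoff)
    d = cdist(np.array([a.coords for a in target.atoms]), pose.coords)
    per_target = d.min(axis=1)
    return ClashReport(count=int((per_target < cutoff).sum()),
                       min_distance=float(per_target.min()), cutoff=cutoff)


def max_intraligand_distance(lig: LigandInstance) -> tuple[float, tuple[str, str]]:
    """Maximum pairwise distance within a ligand and the achieving atom pair.

    A simple conformational span metric: the same compound bound to
    different proteins can differ by several Å in span.
    """
    if len(lig.atoms) < 2:
        raise GeometryError("need at least 2 ligand atoms")
    coords = lig.coords
    d = cdist(coords, coords)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return float(d[i, j]), (lig.atoms[i].name, lig.atoms[j].name)
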