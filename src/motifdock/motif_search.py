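"""Candidate-motif precompilation in a target and congruence search.

A target structure is reduced to its functional atoms (one designated
side-chain atom per residue of the allowed types), and every k-subset whose
pairwise distances all fall within a cutoff is stored as a candidate motif.
A query motif — carrying per-position residue groups, a pairwise distance
matrix and optionally a pairwise potential-difference (PD) matrix — is then
matched against every group-compatible candidate and scored.

The congruence score (CScore; smaller is better, 0 for a self-match) is

    cscore = sum_{i<j} |d_q(ij) - d_c(ij)| / d_q(ij)
           + lambda * sum_{i<j} g(|  |PD_q(ij)| - |PD_c(ij)|  |)

with g(x) = 0 for x < dead-zone (default 100 kT/e), else
(x - dead_zone) / max(|PD_q(ij)|, dead_zone): distance deviations count more
against short reference distances, small PD deviations are ignored, and
large reference PDs are constrained more loosely.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .electrostatics import PotentialAssignment
from .motif_extract import Motif, MotifError, motif_from_atoms
from .structure_io import Atom, Structure

# Designated functional atom per residue type used to seed candidate motifs.
FUNCTIONAL_ATOMS: dict[str, str] = {
    "SER": "OG", "THR": "OG1", "ASP": "OD1", "GLU": "OE1", "TYR": "CZ",
    "TRP": "CZ2", "LYS": "NZ", "ARG": "NH1", "HIS": "NE2", "ASN": "OD1",
    "GLN": "OE1", "CYS": "SG", "PHE": "CZ",
}

DEFAULT_CUTOFF = 15.0   # Å; generous bound on binding-site motif diameter
DEFAULT_S_THRESH = 5.0
PD_DEAD_ZONE = 100.0    # kT/e


class SearchError(Exception):
    pass


class DegenerateMotifError(SearchError):
    pass


@dataclasses.dataclass
class MotifDatabase:
    """All candidate k-subsets of functional atoms within a distance cutoff."""

    target_id: str
    atoms: list[Atom]                       # functional atoms, file order
    entries: list[tuple[int, ...]]          # index k-subsets into ``atoms``
    k: int
    distance_cutoff: float
    allowed_types: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        return json.dumps({
            "format_version": 1,
            "target_id": self.target_id,
            "k": self.k,
            "distance_cutoff": self.distance_cutoff,
            "allowed_types": list(self.allowed_types),
            "atoms": [{"key": a.key, "residue_name": a.residue_name,
                       "name": a.name, "element": a.element,
                       "coords": [round(float(c), 6) for c in a.coords]}
                      for a in self.atoms],
            "entries": [list(e) for e in self.entries],
        })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclasses.dataclass
class CScoreBreakdown:
    """Total congruence score with per-pair contributions."""

    total: float
    distance_term: float
    pd_term: float
    pair_distance_devs: dict[tuple[int, int], float]
    pair_pd_devs: dict[tuple[int, int], float]

    def __float__(self) -> float:
        return self.total


@dataclasses.dataclass
class MatchResult:
    """A group-compatible candidate motif scored against the query."""

    motif: Motif
    cscore: float
    rmsd: float
    maxdev: float
    breakdown: CScoreBreakdown

    @property
    def atom_keys(self) -> tuple[str, ...]:
        return tuple(a.key for a in self.motif.atoms)


def functional_atoms(target: Structure,
                     allowed_types: Sequence[str] | None = None) -> list[Atom]:
    """One designated side-chain atom per residue of the allowed types."""
    allowed = set(allowed_types) if allowed_types is not None else set(FUNCTIONAL_ATOMS)
    out = []
    seen: set[str] = set()
    for atom in target.atoms:
        want = FUNCTIONAL_ATOMS.get(atom.residue_name)
        if (atom.residue_name in allowed and want == atom.name
                and atom.residue_id not in seen):
            seen.add(atom.residue_id)
            out.append(atom)
    return out


def build_database(target: Structure,
                   allowed_types: Sequence[str] | None = None,
                   k: int = 4, cutoff: float = DEFAULT_CUTOFF) -> MotifDatabase:
    """Precompile every k-subset of functional atoms with all pairwise
    distances <= cutoff. Completeness is guaranteed: the enumeration visits
    exactly the subsets a brute-force check over all combinations accepts."""
    if k < 3:
        raise SearchError(f"k must be >= 3, got {k}")
    atoms = functional_atoms(target, allowed_types)
    allowed = tuple(sorted(set(allowed_types))) if allowed_types is not None \
        else tuple(sorted(FUNCTIONAL_ATOMS))
    if not atoms:
        warnings.warn(f"no functional atoms of allowed types in {target.id}; "
                      "database is empty", stacklevel=2)
        return MotifDatabase(target.id, [], [], k, cutoff, allowed)

    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    neighbor = [set(tree.query_ball_point(c, cutoff)) for c in coords]
    entries: list[tuple[int, ...]] = []

    def grow(partial: list[int], candidates: list[int]) -> None:
        if len(partial) == k:
            entries.append(tuple(partial))
            return
        for pos, idx in enumerate(candidates):
            grow(partial + [idx],
                 [c for c in candidates[pos + 1:] if c in neighbor[idx]])

    grow([], list(range(len(atoms))))
    return MotifDatabase(target.id, atoms, entries, k, cutoff, allowed)


def load_database(path: str | Path) -> MotifDatabase:
    payload = json.loads(Path(path).read_text())
    atoms = []
    for i, rec in enumerate(payload["atoms"]):
        chain, resseq, name = rec["key"].split(":")
        seq = int("".join(ch for ch in resseq if ch.isdigit() or ch == "-"))
        icode = "".join(ch for ch in resseq if ch.isalpha())
        atoms.append(Atom(serial=i + 1, name=name, element=rec["element"],
                          residue_name=rec["residue_name"], residue_seq=seq,
                          insertion_code=icode, chain_id=chain, alt_loc="",
                          coords=np.array(rec["coords"])))
    return MotifDatabase(
        target_id=payload["target_id"], atoms=atoms,
        entries=[tuple(e) for e in payload["entries"]],
        k=payload["k"], distance_cutoff=payload["distance_cutoff"],
        allowed_types=tuple(payload["allowed_types"]))


def cscore(query: Motif, candidate: Motif, lam: float = 1.0,
           pd_dead_zone: float = PD_DEAD_ZONE) -> CScoreBreakdown:
    """Congruence score of a candidate against a query motif (0 = identical)."""
    if query.k != candidate.k:
        raise SearchError(f"motif size mismatch: {query.k} vs {candidate.k}")
    k = query.k
    dist_term = 0.0
    pd_term = 0.0
    pair_d: dict[tuple[int, int], float] = {}
    pair_pd: dict[tuple[int, int], float] = {}
    use_pd = query.pds is not None and candidate.pds is not None
    for i, j in itertools.combinations(range(k), 2):
        dq = float(query.distances[i, j])
        dc = float(candidate.distances[i, j])
        if dq <= 0:
            raise DegenerateMotifError(
                f"query pair ({i},{j}) has zero reference distance")
        dev = abs(dq - dc)
        pair_d[(i, j)] = dev
        dist_term += dev / dq
        if use_pd:
            pd_dev = abs(abs(float(query.pds[i, j])) - abs(float(candidate.pds[i, j])))
            pair_pd[(i, j)] = pd_dev
            if pd_dev >= pd_dead_zone:
                pd_term += (pd_dev - pd_dead_zone) / max(
                    abs(float(query.pds[i, j])), pd_dead_zone)
    total = dist_term + lam * pd_term
    return CScoreBreakdown(total=total, distance_term=dist_term,
                           pd_term=lam * pd_term,
                           pair_distance_devs=pair_d, pair_pd_devs=pair_pd)


def max_pairwise_deviation(d_query: np.ndarray, d_candidate: np.ndarray) -> float:
    """Largest |d_q(ij) - d_c(ij)| over atom pairs."""
    dq = np.asarray(d_query, dtype=float)
    dc = np.asarray(d_candidate, dtype=float)
    iu = np.triu_indices(dq.shape[0], k=1)
    return float(np.max(np.abs(dq[iu] - dc[iu])))


def superposition_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid superposition (Kabsch)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise SearchError("need two equal sets of >= 3 points")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s_corr = np.array([1.0, 1.0, d])
    e0 = (a ** 2).sum() + (b ** 2).sum()
    msd = max((e0 - 2.0 * (s * s_corr).sum()) / a.shape[0], 0.0)
    return float(np.sqrt(msd))


def congruence_metrics(query: Motif, candidate: Motif) -> tuple[float, float]:
    """(superposition RMSD, maximum pairwise-distance deviation), both Å."""
    if query.k != candidate.k:
        raise SearchError(f"motif size mismatch: {query.k} vs {candidate.k}")
    if query.k < 3:
        raise SearchError("need k >= 3")
    rmsd = superposition_rmsd(np.array([a.coords for a in query.atoms]),
                              np.array([a.coords for a in candidate.atoms]))
    return rmsd, max_pairwise_deviation(query.distances, candidate.distances)


def _compatible_orderings(entry: tuple[int, ...], atoms: list[Atom],
                          groups: Sequence[frozenset[str]]):
    """Orderings of the entry whose residue type fits each query group."""
    slots = [[i for i in entry if atoms[i].residue_name in g] for g in groups]
    for perm in itertools.product(*slots):
        if len(set(perm)) == len(entry):
            yield perm


def search(db: MotifDatabase, query: Motif,
           s_thresh: float = DEFAULT_S_THRESH,
           potentials: PotentialAssignment | None = None,
           lam: float = 1.0, pd_dead_zone: float = PD_DEAD_ZONE) -> list[MatchResult]:
    """Score every group-compatible candidate; keep cscore <= s_thresh.

    Each stored k-subset is expanded into the orderings whose per-position
    residue type belongs to the query's group at that position; each ordering
    is scored position-to-position and the best ordering represents the
    subset. Results are sorted ascending by cscore (ties broken by atom
    identity for determinism).
    """
    if query.groups is None:
        raise SearchError("query motif has no groups assigned; call assign_groups")
    if db.k != query.k:
        raise SearchError(f"database k={db.k} does not match query k={query.k}")
    results: list[MatchResult] = []
    for entry in db.entries:
        best: MatchResult | None = None
        for perm in _compatible_orderings(entry, db.atoms, query.groups):
            ordered = [db.atoms[i] for i in perm]
            candidate = motif_from_atoms(ordered, potentials=potentials,
                                         source_id=db.target_id)
            breakdown = cscore(query, candidate, lam=lam, pd_dead_zone=pd_dead_zone)
            if best is None or breakdown.total < best.cscore:
                rmsd, maxdev = congruence_metrics(query, candidate)
                best = MatchResult(motif=candidate, cscore=breakdown.total,
                                   rmsd=rmsd, maxdev=maxdev, breakdown=breakdown)
        if best is not None and best.cscore <= s_thresh:
            results.append(best)
    results.sort(key=lambda r: (r.cscore, r.atom_keys))
    return results


def matches_to_tsv(query: Motif, matches: Sequence[MatchResult],
                   header_lines: Sequence[str] = ()) -> str:
    """Export ranked matches in the congruence-table layout (one row per
    motif: atoms, per-pair D deviations, cscore, rmsd, max)."""
    k = query.k
    pair_names = ["".join(chr(ord("a") + x) for x in (i, j))
                  for i, j in itertools.combinations(range(k), 2)]
    lines = [f"# {h}" for h in header_lines]
    lines.append("# query: " + ",".join(a.key for a in query.atoms))
    lines.append("rank\tatoms\t" + "\t".join(f"dD_{p}" for p in pair_names)
                 + "\tcscore\trmsd_A\tmax_A")
    for rank, m in enumerate(matches, start=1):
        devs = "\t".join(f"{m.breakdown.pair_distance_devs[(i, j)]:.2f}"
                         for i, j in itertools.combinations(range(k), 2))
        lines.append(f"{rank}\t{','.join(m.atom_keys)}\t{devs}\t"
                     f"{m.cscore:.3f}\t{m.rmsd:.2f}\t{m.maxdev:.2f}")
    return "\n".join(lines) + "\n"
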