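"""Per-atom electrostatic potentials and pairwise potential differences.

The congruence score compares pairwise potential differences (PD, in kT/e)
between motif atoms. Potentials are pluggable: they may be interpolated from
a Poisson-Boltzmann potential grid (OpenDX scalar field, the APBS output
dialect), read from a per-atom table, or computed internally with a
screened-Coulomb surrogate over a bundled formal-charge assignment. The
surrogate exists so the whole scoring pipeline is exercisable without any
external solver; its absolute values are not Poisson-Boltzmann potentials,
but its sign structure and orderings behave like a real field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist

from .structure_io import Atom, Structure


class PotentialError(Exception):
    pass


class GridParseError(PotentialError):
    pass


class OutOfBoundsError(PotentialError):
    pass


class MissingPotentialError(PotentialError):
    pass


# Formal side-chain charges (units of e), split over the terminal atoms that
# carry them. His is neutral by default. Override by passing your own table.
DEFAULT_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
}


@dataclasses.dataclass
class PotentialGrid:
    """A regular scalar grid (potential in kT/e on grid nodes)."""

    origin: np.ndarray          # (3,) Å
    delta: np.ndarray           # (3,) Å spacing along each axis
    counts: tuple[int, int, int]
    values: np.ndarray          # shape counts, x-major (z fastest in file)

    def __post_init__(self) -> None:
        self._interp = RegularGridInterpolator(
            tuple(self.origin[i] + self.delta[i] * np.arange(self.counts[i])
                  for i in range(3)),
            self.values, method="linear", bounds_error=True)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points (Å); strict bounds."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        try:
            return self._interp(pts)
        except ValueError as exc:
            raise OutOfBoundsError(f"query outside grid bounds: {exc}") from exc


def load_potential_grid(path: str | Path) -> PotentialGrid:
    """Read an OpenDX scalar-grid file (APBS dialect)."""
    counts = origin = None
    deltas: list[np.ndarray] = []
    data: list[float] = []
    n_items = None
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if in_data:
            if line.startswith(("attribute", "component", "object", "end")):
                in_data = False
                continue
            data.extend(float(tok) for tok in line.split())
            continue
        tokens = line.split()
        if line.startswith("object") and "gridpositions" in line:
            counts = tuple(int(t) for t in tokens[-3:])
        elif line.startswith("origin"):
            origin = np.array([float(t) for t in tokens[1:4]])
        elif line.startswith("delta"):
            deltas.append(np.array([float(t) for t in tokens[1:4]]))
        elif line.startswith("object") and "class array" in line:
            try:
                n_items = int(tokens[tokens.index("items") + 1])
            except (ValueError, IndexError) as exc:
                raise GridParseError(f"malformed array header: {line!r}") from exc
            in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise GridParseError("missing gridpositions/origin/delta records")
    delta_mat = np.vstack(deltas)
    if not np.allclose(delta_mat, np.diag(np.diag(delta_mat))):
        raise GridParseError("only axis-aligned grids are supported")
    values = np.asarray(data, dtype=float)
    expected = counts[0] * counts[1] * counts[2]
    if n_items is not None and n_items != expected:
        raise GridParseError(f"header says {n_items} items, counts imply {expected}")
    if values.size != expected:
        raise GridParseError(f"found {values.size} values, expected {expected}")
    return PotentialGrid(origin=origin, delta=np.diag(delta_mat),
                         counts=counts, values=values.reshape(counts))


@dataclasses.dataclass(frozen=True)
class SurrogateParams:
    """Screened-Coulomb settings: phi(i) = sum_j q_j exp(-kappa r_ij)/(eps_r r_ij)
    over all charged atoms j with r_ij > self_exclusion."""

    kappa: float = 0.1          # inverse screening length, 1/Å
    eps_r: float = 10.0         # relative dielectric
    self_exclusion: float = 0.1  # Å; atoms closer than this do not contribute
    charges: Mapping[tuple[str, str], float] | None = None


@dataclasses.dataclass
class PotentialAssignment:
    """Per-atom scalar potential (kT/e) keyed by atom identity."""

    values: dict[str, float]
    source: str                 # grid | table | surrogate
    parameters: dict

    def get(self, atom: Atom) -> float:
        try:
            return self.values[atom.key]
        except KeyError:
            raise MissingPotentialError(
                f"no potential assigned for atom {atom.key}") from None


def _surrogate_potentials(atoms: Sequence[Atom], params: SurrogateParams) -> dict[str, float]:
    table = dict(DEFAULT_CHARGES if params.charges is None else params.charges)
    charged = [(a.coords, table[(a.residue_name, a.name)])
               for a in atoms if (a.residue_name, a.name) in table]
    coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
    if not charged:
        return {a.key: 0.0 for a in atoms}
    src = np.array([c for c, _ in charged])
    q = np.array([qv for _, qv in charged])
    r = cdist(coords, src)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = q * np.exp(-params.kappa * r) / (params.eps_r * r)
    contrib[r <= params.self_exclusion] = 0.0
    phi = contrib.sum(axis=1)
    return {a.key: float(p) for a, p in zip(atoms, phi)}


def assign_potentials(s: Structure | Sequence[Atom],
                      source: PotentialGrid | Mapping[str, float] | str | Path
                      | SurrogateParams | None = None,
                      include_ligands: bool = False) -> PotentialAssignment:
    """Assign one potential per atom from a grid, a table, or the surrogate.

    ``source`` may be a :class:`PotentialGrid`, a mapping ``atom.key ->
    potential``, a path to a per-atom TSV (chain, resseq, resname, atomname,
    potential), or :class:`SurrogateParams` (default: surrogate with default
    settings). Table sources must cover every atom requested.
    """
    if isinstance(s, Structure):
        atoms = list(s.atoms)
        if include_ligands:
            for lig in s.ligands:
                atoms.extend(lig.atoms)
    else:
        atoms = list(s)

    if source is None:
        source = SurrogateParams()

    if isinstance(source, SurrogateParams):
        values = _surrogate_potentials(atoms, source)
        return PotentialAssignment(values=values, source="surrogate",
                                   parameters=dataclasses.asdict(source) | {"charges": None})
    if isinstance(source, PotentialGrid):
        coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
        phi = source.interpolate(coords)
        return PotentialAssignment(
            values={a.key: float(p) for a, p in zip(atoms, phi)},
            source="grid", parameters={"counts": source.counts})
    if isinstance(source, (str, Path)):
        source = read_potential_table(source)
    values = {}
    for atom in atoms:
        if atom.key not in source:
            raise MissingPotentialError(f"table source lacks atom {atom.key}")
        values[atom.key] = float(source[atom.key])
    return PotentialAssignment(values=values, source="table", parameters={})


def read_potential_table(path: str | Path) -> dict[str, float]:
    """Read a per-atom potential TSV: chain, resseq, resname, atomname, potential."""
    out: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        chain, resseq, _resname, atomname, pot = line.split("\t")[:5]
        out[f"{chain}:{resseq}:{atomname}"] = float(pot)
    return out


def write_potential_table(assignment: PotentialAssignment,
                          atoms: Sequence[Atom], path: str | Path) -> None:
    lines = ["# chain\tresseq\tresname\tatomname\tpotential_kT_e"]
    for a in atoms:
        lines.append(f"{a.chain_id}\t{a.residue_seq}{a.insertion_code.strip()}\t"
                     f"{a.residue_name}\t{a.name}\t{assignment.get(a):.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pqr_charges(path: str | Path) -> dict[str, float]:
    """Read per-atom charges from a PQR file (whitespace-separated PDB-like
    records ending in charge and radius). Returns ``atom.key -> charge``."""
    out: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.startswith(("ATOM", "HETATM")):
            continue
        tokens = raw.split()
        # chain id is optional in PQR; detect by whether token 5 is an integer
        try:
            int(tokens[5])
            chain, resseq = tokens[4], tokens[5]
            charge = float(tokens[9])
        except (ValueError, IndexError):
            chain, resseq = "", tokens[4]
            charge = float(tokens[8])
        out[f"{chain}:{resseq}:{tokens[2]}"] = charge
    return out


def pairwise_pd(assignment: PotentialAssignment, atoms: Sequence[Atom]) -> np.ndarray:
    """PD matrix: PD[i, j] = phi(i) - phi(j). Antisymmetric, zero diagonal."""
    phi = np.array([assignment.get(a) for a in atoms])
    return phi[:, None] - phi[None, :]
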