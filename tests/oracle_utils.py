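"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct route possible
(exhaustive enumeration, closed forms) and never call the code paths they
are used to check.
"""

import itertools

import numpy as np

ACCEPTED = {("O", "N"), ("N", "O"), ("O", "H"), ("H", "O"), ("O", "O"),
            ("N", "N"), ("N", "H"), ("H", "N"), ("S", "H"), ("H", "S")}


def brute_force_motif(protein_atoms, ligand_atoms, n, radius_cap=8.0):
    """Sort all pairs by distance, filter by the polar whitelist, dedupe by
    residue, take the first n. Returns (protein atom key, ligand atom name,
    distance) tuples, or None if fewer than n qualify."""
    pairs = []
    for la in ligand_atoms:
        for pa in protein_atoms:
            if (la.element, pa.element) not in ACCEPTED:
                continue
            d = float(np.linalg.norm(la.coords - pa.coords))
            if d <= radius_cap:
                pairs.append((d, pa, la))
    pairs.sort(key=lambda t: (t[0], t[1].chain_id, t[1].residue_seq, t[1].name))
    out, seen = [], set()
    for d, pa, la in pairs:
        if pa.residue_id in seen:
            continue
        seen.add(pa.residue_id)
        out.append((pa.key, la.name, d))
        if len(out) == n:
            return out
    return None


def brute_force_database(atoms, k, cutoff):
    """All k-subsets (as index tuples) with every pairwise distance <= cutoff."""
    coords = np.array([a.coords for a in atoms])
    out = []
    for combo in itertools.combinations(range(len(atoms)), k):
        ok = all(np.linalg.norm(coords[i] - coords[j]) <= cutoff
                 for i, j in itertools.combinations(combo, 2))
        if ok:
            out.append(tuple(combo))
    return out


def brute_force_cscore(d_query, d_candidate, pd_query=None, pd_candidate=None,
                       lam=1.0, dead_zone=100.0):
    """The congruence score, written out directly from its definition."""
    k = d_query.shape[0]
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += abs(d_query[i, j] - d_candidate[i, j]) / d_query[i, j]
            if pd_query is not None and pd_candidate is not None:
                dev = abs(abs(pd_query[i, j]) - abs(pd_candidate[i, j]))
                if dev >= dead_zone:
                    total += lam * (dev - dead_zone) / max(abs(pd_query[i, j]),
                                                           dead_zone)
    return total


def brute_force_search(db_atoms, entries, query, s_thresh, lam=1.0):
    """Exhaustive group-compatible ordering enumeration + direct scoring.

    Returns [(atom keys tuple, cscore)] sorted ascending, best ordering per
    stored subset, survivors of the threshold only.
    """
    results = []
    for entry in entries:
        best = None
        for perm in itertools.permutations(entry):
            if any(db_atoms[idx].residue_name not in group
                   for idx, group in zip(perm, query.groups)):
                continue
            coords = np.array([db_atoms[idx].coords for idx in perm])
            dc = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            score = brute_force_cscore(query.distances, dc, lam=lam)
            keys = tuple(db_atoms[idx].key for idx in perm)
            if best is None or score < best[1]:
                best = (keys, score)
        if best is not None and best[1] <= s_thresh:
            results.append(best)
    results.sort(key=lambda t: (t[1], t[0]))
    return results


def random_contact_scene(rng, n_protein=40, n_ligand=6):
    """A random cloud of protein atoms (mixed elements/residues) and a
    random polar-ish ligand, for adversarial motif-extraction tests."""
    from conftest import make_atom

    elements = ["N", "O", "C", "S"]
    resnames = ["SER", "ASP", "LYS", "GLY", "TYR", "HIS"]
    protein = []
    for i in range(n_protein):
        # several atoms may share a residue to exercise residue dedup
        resseq = int(rng.integers(1, max(n_protein // 2, 2)))
        protein.append(make_atom(
            name=f"X{i}", element=elements[int(rng.integers(4))],
            residue_name=resnames[int(rng.integers(len(resnames)))],
            residue_seq=resseq, serial=i + 1,
            coords=rng.uniform(-6, 6, size=3)))
    ligand = [make_atom(name=f"L{i}", element=elements[int(rng.integers(3))],
                        residue_name="LIG", residue_seq=900, serial=200 + i,
                        is_hetero=True, coords=rng.uniform(-2, 2, size=3))
              for i in range(n_ligand)]
    return protein, ligand
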