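import itertools

import numpy as np
import pytest

import motifdock as md
from motifdock.motif_search import (DegenerateMotifError, SearchError,
                                    cscore, max_pairwise_deviation,
                                    superposition_rmsd)
from motifdock.structure_io import Structure

from conftest import make_atom
from oracle_utils import (brute_force_cscore, brute_force_database,
                          brute_force_search)


def functional_structure(positions, res_types=None):
    """One residue per position, carrying only its designated functional atom."""
    from motifdock.motif_search import FUNCTIONAL_ATOMS
    res_types = res_types or ["SER"] * len(positions)
    atoms = []
    for i, (pos, rt) in enumerate(zip(positions, res_types)):
        name = FUNCTIONAL_ATOMS[rt]
        element = "O" if name.startswith("O") else ("N" if name.startswith("N")
                                                    else name[0])
        atoms.append(make_atom(name=name, element=element, residue_name=rt,
                               residue_seq=i + 1, coords=pos, serial=i + 1))
    return Structure(id="F", atoms=atoms, ligands=[])


def motif_with_matrices(d, pds=None, res_types=("SER", "ASP", "GLU")):
    """A motif whose feature matrices are set directly (coords unused)."""
    k = np.asarray(d).shape[0]
    atoms = [make_atom(name=f"O{i}", residue_name=rt, residue_seq=i + 1,
                       coords=(3.0 * i, 0, 0))
             for i, rt in zip(range(k), res_types)]
    return md.Motif(atoms=tuple(atoms), distances=np.asarray(d, float),
                    pds=None if pds is None else np.asarray(pds, float))


def sym(k, pairs):
    m = np.zeros((k, k))
    for (i, j), v in pairs.items():
        m[i, j] = m[j, i] = v
    return m


class TestBuildDatabase:
    def test_five_close_serines_give_all_four_subsets(self, rng):
        pos = rng.uniform(0, 6, size=(5, 3))
        db = md.build_database(functional_structure(pos), k=4, cutoff=15.0)
        assert len(db) == 5

    def test_tiny_cutoff_gives_empty_database(self, rng):
        pos = rng.uniform(0, 6, size=(5, 3))
        db = md.build_database(functional_structure(pos), k=4, cutoff=0.1)
        assert len(db) == 0

    def test_remote_residue_appears_in_no_motif(self, rng):
        pos = np.vstack([rng.uniform(0, 6, size=(5, 3)), [[50.0, 0, 0]]])
        db = md.build_database(functional_structure(pos), k=4, cutoff=15.0)
        far_index = 5
        assert all(far_index not in entry for entry in db.entries)

    @pytest.mark.parametrize("n_res,k,cutoff", [(8, 3, 6.0), (10, 4, 8.0),
                                                (12, 4, 10.0), (12, 5, 12.0)])
    def test_completeness_matches_brute_force(self, rng, n_res, k, cutoff):
        pos = rng.uniform(0, 14, size=(n_res, 3))
        s = functional_structure(pos)
        db = md.build_database(s, k=k, cutoff=cutoff)
        expected = brute_force_database(db.atoms, k, cutoff)
        assert sorted(db.entries) == sorted(expected)

    def test_no_functional_residues_warns_and_is_empty(self):
        s = Structure(id="E", atoms=[make_atom(name="CB", element="C",
                                               residue_name="ALA")], ligands=[])
        with pytest.warns(UserWarning):
            db = md.build_database(s, k=4)
        assert len(db) == 0

    def test_save_load_roundtrip(self, rng, tmp_path):
        pos = rng.uniform(0, 8, size=(6, 3))
        db = md.build_database(functional_structure(pos), k=4, cutoff=12.0)
        db.save(tmp_path / "db.json")
        again = md.load_database(tmp_path / "db.json")
        assert again.entries == db.entries
        assert [a.key for a in again.atoms] == [a.key for a in db.atoms]
        np.testing.assert_allclose(
            np.array([a.coords for a in again.atoms]),
            np.array([a.coords for a in db.atoms]), atol=1e-6)


class TestCScore:
    def test_identical_matrices_score_zero(self):
        d = sym(3, {(0, 1): 4.0, (0, 2): 5.0, (1, 2): 6.0})
        q = motif_with_matrices(d)
        assert cscore(q, motif_with_matrices(d)).total == 0.0

    def test_distance_only_worked_example(self):
        # one pair off by 1 Å against a 4 Å reference: 1/4
        dq = sym(3, {(0, 1): 4.0, (0, 2): 5.0, (1, 2): 6.0})
        dc = sym(3, {(0, 1): 5.0, (0, 2): 5.0, (1, 2): 6.0})
        res = cscore(motif_with_matrices(dq), motif_with_matrices(dc))
        assert res.total == pytest.approx(0.25)
        assert res.pd_term == 0.0

    def test_pd_deviation_inside_dead_zone_is_free(self):
        d = sym(3, {(0, 1): 4.0, (0, 2): 5.0, (1, 2): 6.0})
        pq = sym(3, {(0, 1): 300.0, (0, 2): 300.0, (1, 2): 300.0})
        pc = sym(3, {(0, 1): 250.0, (0, 2): 220.0, (1, 2): 390.0})
        res = cscore(motif_with_matrices(d, pq), motif_with_matrices(d, pc))
        assert res.total == 0.0

    def test_pd_deviation_beyond_dead_zone_scaled_by_reference(self):
        d = sym(3, {(0, 1): 4.0, (0, 2): 5.0, (1, 2): 6.0})
        pq = sym(3, {(0, 1): 300.0, (0, 2): 300.0, (1, 2): 300.0})
        pc = sym(3, {(0, 1): 450.0, (0, 2): 300.0, (1, 2): 300.0})
        res = cscore(motif_with_matrices(d, pq), motif_with_matrices(d, pc))
        assert res.total == pytest.approx((150.0 - 100.0) / 300.0)

    def test_pd_sign_is_ignored(self):
        d = sym(3, {(0, 1): 4.0, (0, 2): 5.0, (1, 2): 6.0})
        pq = sym(3, {(0, 1): 300.0, (0, 2): -150.0, (1, 2): 80.0})
        pc = -pq
        res = cscore(motif_with_matrices(d, pq), motif_with_matrices(d, pc))
        assert res.total == 0.0

    def test_doubling_a_candidate_distance_strictly_increases_score(self):
        dq = sym(3, {(0, 1): 4.0, (0, 2): 5.0, (1, 2): 6.0})
        dc = sym(3, {(0, 1): 4.5, (0, 2): 5.0, (1, 2): 6.0})
        dc2 = dc.copy()
        dc2[0, 1] = dc2[1, 0] = 9.0
        q = motif_with_matrices(dq)
        assert cscore(q, motif_with_matrices(dc2)).total > \
            cscore(q, motif_with_matrices(dc)).total

    def test_zero_reference_distance_is_degenerate(self):
        dq = sym(3, {(0, 1): 0.0, (0, 2): 5.0, (1, 2): 6.0})
        with pytest.raises(DegenerateMotifError):
            cscore(motif_with_matrices(dq), motif_with_matrices(dq))

    def test_matches_direct_formula_on_random_matrices(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 6))
            pos_q = rng.uniform(0, 10, (k, 3))
            pos_c = rng.uniform(0, 10, (k, 3))
            dq = np.linalg.norm(pos_q[:, None] - pos_q[None], axis=-1)
            dc = np.linalg.norm(pos_c[:, None] - pos_c[None], axis=-1)
            pq = sym(k, {(i, j): rng.uniform(-500, 500)
                         for i, j in itertools.combinations(range(k), 2)})
            pc = sym(k, {(i, j): rng.uniform(-500, 500)
                         for i, j in itertools.combinations(range(k), 2)})
            res = cscore(motif_with_matrices(dq, pq, res_types=["SER"] * k),
                         motif_with_matrices(dc, pc, res_types=["SER"] * k))
            assert res.total == pytest.approx(
                brute_force_cscore(dq, dc, pq, pc), rel=1e-12)


class TestCongruenceMetrics:
    def test_rotated_copy_has_zero_rmsd_and_maxdev(self, rng):
        pos = rng.uniform(0, 8, size=(4, 3))
        theta = 0.9
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = pos @ rot.T + np.array([3, -2, 7])
        q = md.motif_from_atoms([make_atom(name=f"O{i}", residue_seq=i + 1,
                                           coords=c) for i, c in enumerate(pos)])
        c = md.motif_from_atoms([make_atom(name=f"O{i}", residue_seq=i + 1,
                                           coords=cc) for i, cc in enumerate(moved)])
        rmsd, maxdev = md.congruence_metrics(q, c)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert maxdev == pytest.approx(0.0, abs=1e-9)

    def test_lengthened_triangle_edge_reports_its_deviation(self):
        a = [(0, 0, 0), (3, 0, 0), (0, 4, 0)]
        b = [(0, 0, 0), (5, 0, 0), (0, 4, 0)]      # one edge +2 Å
        q = md.motif_from_atoms([make_atom(name=f"O{i}", residue_seq=i + 1,
                                           coords=c) for i, c in enumerate(a)])
        c = md.motif_from_atoms([make_atom(name=f"O{i}", residue_seq=i + 1,
                                           coords=cc) for i, cc in enumerate(b)])
        _, maxdev = md.congruence_metrics(q, c)
        assert maxdev == pytest.approx(2.0)

    def test_published_style_pair_arithmetic(self):
        # four-atom motifs described only by their six pair distances
        dq = sym(4, {(0, 1): 9.5, (0, 2): 7.8, (0, 3): 11.2,
                     (1, 2): 7.2, (1, 3): 6.6, (2, 3): 5.8})
        dc = sym(4, {(0, 1): 4.3, (0, 2): 6.7, (0, 3): 10.1,
                     (1, 2): 6.7, (1, 3): 7.7, (2, 3): 4.9})
        assert max_pairwise_deviation(dq, dc) == pytest.approx(5.2)

    def test_rmsd_invariant_under_rigid_motion_of_either_side(self, rng):
        pos_q = rng.uniform(0, 8, size=(4, 3))
        pos_c = rng.uniform(0, 8, size=(4, 3))
        base = superposition_rmsd(pos_q, pos_c)
        theta = 0.4
        rot = np.array([[1, 0, 0], [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        assert superposition_rmsd(pos_q @ rot.T + 5.0, pos_c) == \
            pytest.approx(base, abs=1e-9)
        assert superposition_rmsd(pos_q, pos_c @ rot.T - 2.0) == \
            pytest.approx(base, abs=1e-9)

    def test_requires_at_least_three_points(self):
        with pytest.raises(SearchError):
            superposition_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSearch:
    @staticmethod
    def _query_from(structure, indices, res_types=None):
        atoms = [structure.atoms[i] for i in indices]
        return md.assign_groups(md.motif_from_atoms(atoms))

    def test_self_match_scores_zero_and_ranks_first(self, rng):
        pos = rng.uniform(0, 9, size=(7, 3))
        types = ["SER", "ASP", "GLU", "LYS", "ASN", "TYR", "HIS"]
        s = functional_structure(pos, types)
        db = md.build_database(s, k=4, cutoff=25.0)
        query = self._query_from(s, [0, 1, 2, 3])
        matches = md.search(db, query, s_thresh=5.0)
        assert matches[0].cscore == pytest.approx(0.0, abs=1e-9)
        assert set(matches[0].atom_keys) == {s.atoms[i].key for i in range(4)}
        assert matches[0].rmsd == pytest.approx(0.0, abs=1e-6)

    def test_results_sorted_and_threshold_never_reorders(self, rng):
        pos = rng.uniform(0, 10, size=(9, 3))
        types = ["SER", "ASP", "GLU", "LYS", "ASN", "SER", "ASP", "GLU", "LYS"]
        s = functional_structure(pos, types)
        db = md.build_database(s, k=4, cutoff=30.0)
        query = self._query_from(s, [0, 1, 2, 3])
        full = md.search(db, query, s_thresh=np.inf)
        scores = [m.cscore for m in full]
        assert scores == sorted(scores)
        cut = md.search(db, query, s_thresh=scores[len(scores) // 2])
        assert [m.atom_keys for m in cut] == \
            [m.atom_keys for m in full[:len(cut)]]

    def test_group_filter_excludes_incompatible_residues(self, rng):
        pos = rng.uniform(0, 6, size=(4, 3))
        s = functional_structure(pos, ["TYR", "TYR", "TYR", "TYR"])
        db = md.build_database(s, k=4, cutoff=30.0)
        query_struct = functional_structure(rng.uniform(0, 6, size=(4, 3)),
                                            ["SER", "ASP", "GLU", "LYS"])
        query = self._query_from(query_struct, [0, 1, 2, 3])
        assert md.search(db, query, s_thresh=np.inf) == []

    def test_substituted_residue_matches_through_its_group(self, rng):
        pos = rng.uniform(0, 8, size=(4, 3))
        s_glu = functional_structure(pos, ["SER", "GLU", "LYS", "ASN"])
        # same geometry, Glu replaced by Asp (OD1 also oxygen)
        s_asp = functional_structure(pos, ["SER", "ASP", "LYS", "ASN"])
        db = md.build_database(s_asp, k=4, cutoff=30.0)
        query = self._query_from(s_glu, [0, 1, 2, 3])
        matches = md.search(db, query, s_thresh=5.0)
        assert matches and matches[0].cscore == pytest.approx(0.0, abs=1e-9)
        assert matches[0].motif.atoms[1].residue_name == "ASP"

    def test_matches_exhaustive_oracle_on_thirty_residues(self, rng):
        pos = rng.uniform(0, 18, size=(30, 3))
        types = [["SER", "ASP", "GLU", "LYS", "ASN", "TYR"][i % 6]
                 for i in range(30)]
        s = functional_structure(pos, types)
        db = md.build_database(s, k=4, cutoff=12.0)
        query = self._query_from(s, [0, 1, 2, 3])
        got = md.search(db, query, s_thresh=3.0)
        expected = brute_force_search(db.atoms, db.entries, query, s_thresh=3.0)
        assert [m.atom_keys for m in got] == [keys for keys, _ in expected]
        np.testing.assert_allclose([m.cscore for m in got],
                                   [sc for _, sc in expected], rtol=1e-10)

    def test_k_mismatch_raises(self, rng):
        pos = rng.uniform(0, 9, size=(5, 3))
        s = functional_structure(pos, ["SER", "ASP", "GLU", "LYS", "ASN"])
        db = md.build_database(s, k=4, cutoff=30.0)
        query = self._query_from(s, [0, 1, 2])
        with pytest.raises(SearchError):
            md.search(db, query)

    def test_query_without_groups_raises(self, rng):
        pos = rng.uniform(0, 9, size=(4, 3))
        s = functional_structure(pos, ["SER", "ASP", "GLU", "LYS"])
        db = md.build_database(s, k=4, cutoff=30.0)
        bare = md.motif_from_atoms(s.atoms)
        with pytest.raises(SearchError):
            md.search(db, bare)

    def test_maxdev_bounds_every_per_pair_deviation(self, rng):
        pos = rng.uniform(0, 10, size=(8, 3))
        types = ["SER", "ASP", "GLU", "LYS", "ASN", "SER", "ASP", "GLU"]
        s = functional_structure(pos, types)
        db = md.build_database(s, k=4, cutoff=30.0)
        query = self._query_from(s, [0, 1, 2, 3])
        for m in md.search(db, query, s_thresh=np.inf):
            devs = list(m.breakdown.pair_distance_devs.values())
            assert m.maxdev == pytest.approx(max(devs), abs=1e-9)
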