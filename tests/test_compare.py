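import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from trajscape.compare import (
    domain_rotation,
    ligand_contacts,
    match_atoms,
    min_distance,
    superpose,
)
from trajscape.model_io import AtomIndexSet, select
from trajscape.synthetic import make_bundle, make_rotated_complex

from conftest import build_structure


def rigid_copy(st, angle_deg=25.0, axis=(1, 0.5, -0.2), shift=(4.0, -7.0, 2.0)):
    R = Rotation.from_rotvec(np.radians(angle_deg) * np.array(axis) / np.linalg.norm(axis)).as_matrix()
    return st.with_coordinates(st.coordinates @ R.T + np.asarray(shift))


def test_self_superposition_is_identity(bundle):
    ca = select(bundle, "calpha")
    res = superpose(bundle, bundle, ca, ca)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
    assert res.n_atoms_used == len(ca)


def test_translated_copy_superposes_exactly(bundle):
    ca = select(bundle, "calpha")
    moved = bundle.with_coordinates(bundle.coordinates + np.array([5.0, -2.0, 9.0]))
    res = superpose(moved, bundle, ca, ca)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)


def test_rmsd_matches_grid_refine_oracle():
    rng = np.random.default_rng(31)
    pts = rng.uniform(-4, 4, size=(4, 3))
    st = build_structure([("CA", "C", "ALA", i + 1, pts[i]) for i in range(4)])
    noisy = st.with_coordinates(pts + rng.normal(0, 0.5, (4, 3)))
    ca = select(st, "calpha")
    res = superpose(noisy, st, ca, ca)

    a = st.coordinates - st.coordinates.mean(axis=0)
    b = noisy.coordinates - noisy.coordinates.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((b @ R.T - a) ** 2, axis=1)))

    best = min(
        (rmsd_of([x, y, z]), [x, y, z])
        for x in np.linspace(-np.pi, np.pi, 9)
        for y in np.linspace(-np.pi, np.pi, 9)
        for z in np.linspace(-np.pi, np.pi, 9)
    )
    ref = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12}).fun
    assert res.rmsd == pytest.approx(min(best[0], ref), abs=1e-3)


def test_rmsd_symmetric_and_rigid_invariant(bundle):
    rng = np.random.default_rng(5)
    ca = select(bundle, "calpha")
    other = bundle.with_coordinates(bundle.coordinates + rng.normal(0, 0.8, bundle.coordinates.shape))
    r_ab = superpose(bundle, other, ca, ca).rmsd
    r_ba = superpose(other, bundle, ca, ca).rmsd
    assert r_ab == pytest.approx(r_ba, abs=1e-9)
    assert superpose(rigid_copy(other), bundle, ca, ca).rmsd == pytest.approx(r_ab, abs=1e-9)


def test_degenerate_point_sets_rejected():
    st = build_structure([("CA", "C", "ALA", i + 1, (float(i), 0, 0)) for i in range(4)])
    ca = select(st, "calpha")
    with pytest.raises(ValueError, match="degenerate"):
        superpose(st, st, ca, ca)


class TestDomainRotation:
    def pairings(self, a, b):
        align = "calpha and resid 11-40"
        dom = "calpha and resid 1-10"
        return ((select(a, align), select(b, align)),
                (select(a, dom), select(b, dom)))

    def test_identical_structures_zero(self, bundle):
        align, dom = self.pairings(bundle, bundle)
        assert domain_rotation(bundle, bundle, align, dom) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [5.0, 30.0, 64.0, 90.0, 135.0, 175.0])
    def test_planted_angle_recovered(self, bundle, angle):
        dom_sel = select(bundle, "resid 1-10")
        rotated = make_rotated_complex(bundle, dom_sel, angle, [0.3, 1.0, 0.2])
        align, dom = self.pairings(bundle, rotated)
        got = domain_rotation(bundle, rotated, align, dom)
        assert got == pytest.approx(angle, abs=1e-6)

    def test_invariant_to_global_motion(self, bundle):
        dom_sel = select(bundle, "resid 1-10")
        rotated = make_rotated_complex(bundle, dom_sel, 64.0, [0, 0, 1])
        moved = rigid_copy(rotated)
        align, dom = self.pairings(bundle, moved)
        assert domain_rotation(bundle, moved, align, dom) == pytest.approx(64.0, abs=1e-6)


class TestLigandContacts:
    @staticmethod
    def pocket(lig_offset):
        return build_structure([
            ("CA", "C", "PHE", 268, (0, 0, 0)),
            ("CZ", "C", "PHE", 268, (1.4, 0, 0)),
            ("CA", "C", "TRP", 356, (0, 8, 0)),
            ("NE1", "N", "TRP", 356, (1.0, 8, 0)),
            ("C1", "C", "LIG", 900, lig_offset, True),
        ])

    def test_far_ligand_gives_empty_table(self):
        st = self.pocket((50.0, 50.0, 50.0))
        table = ligand_contacts(st, select(st, "hetero"), cutoff=4.0)
        assert len(table) == 0

    def test_planted_distance_reported(self):
        st = self.pocket((1.4 + 3.3, 0.0, 0.0))  # 3.3 Å from PHE CZ
        table = ligand_contacts(st, select(st, "hetero"), cutoff=4.0)
        assert table.residues() == [("A", 268, "PHE")]
        row = table.rows.iloc[0]
        assert row.min_distance == pytest.approx(3.30, abs=1e-9)
        assert (row.atom_a, row.atom_b) == ("CZ", "C1")

    def test_matches_brute_force(self, bundle):
        rng = np.random.default_rng(3)
        lig_xyz = bundle.coordinates.mean(axis=0)
        from trajscape.model_io import Atom, Structure

        atoms = list(bundle.atoms) + [
            Atom(9000 + i, f"L{i}", "C", "LIG", 900, "A",
                 lig_xyz + rng.normal(0, 2.0, 3), is_hetero=True)
            for i in range(3)
        ]
        st = Structure(atoms)
        lig = select(st, "hetero")
        table = ligand_contacts(st, lig, cutoff=4.0)
        lig_idx = set(lig.indices)
        expected = set()
        for i, a in enumerate(st.atoms):
            if i in lig_idx or a.is_hydrogen:
                continue
            for j in lig.indices:
                if np.linalg.norm(a.coordinates - st.atoms[j].coordinates) <= 4.0:
                    expected.add(a.residue_key)
        assert set(table.residues()) == expected
        assert list(table.rows.min_distance) == sorted(table.rows.min_distance)


class TestMinDistance:
    def test_coincident_distinct_atoms(self):
        st = build_structure([
            ("A1", "C", "LIG", 1, (0, 0, 0), True),
            ("B1", "C", "LIG", 2, (0, 0, 0), True),
        ])
        d, pair = min_distance(st, AtomIndexSet(np.array([0])), AtomIndexSet(np.array([1])))
        assert d == 0.0
        assert pair == (0, 1)

    def test_enumerated_distances(self):
        st = build_structure([
            ("A1", "C", "LIG", 1, (0, 0, 0), True),
            ("A2", "C", "LIG", 1, (0, 5, 0), True),
            ("B1", "C", "LIG", 2, (2.5, 0, 0), True),
            ("B2", "C", "LIG", 2, (0, 5, 3.7), True),
            ("B3", "C", "LIG", 2, (9.0, 0, 0), True),
        ])
        d, pair = min_distance(st, AtomIndexSet(np.array([0, 1])),
                               AtomIndexSet(np.array([2, 3, 4])))
        assert d == pytest.approx(2.5, abs=1e-12)
        assert pair == (0, 2)

    def test_overlap_and_empty_rejected(self, bundle):
        a = AtomIndexSet(np.array([0, 1]))
        with pytest.raises(ValueError, match="overlap"):
            min_distance(bundle, a, AtomIndexSet(np.array([1, 2])))
        with pytest.raises(ValueError, match="non-empty"):
            min_distance(bundle, a, AtomIndexSet(np.array([], dtype=int)))


def test_match_atoms_drops_unmatched(bundle):
    small = make_bundle(4, 8, seed=1)  # fewer residues, same numbering start
    sel_m, sel_r = match_atoms(bundle, small)
    assert len(sel_m) == len(sel_r)
    assert len(sel_m) < 40  # bundle has 40 residues, the overlap is smaller
    keys_m = [(bundle.atoms[i].chain_id, bundle.atoms[i].residue_number) for i in sel_m]
    keys_r = [(small.atoms[i].chain_id, small.atoms[i].residue_number) for i in sel_r]
    assert keys_m == keys_r
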