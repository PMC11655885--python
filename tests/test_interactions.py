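import numpy as np
import pytest

from trajscape.interactions import (
    InteractionEdge,
    InteractionNetwork,
    InteractionParams,
    frame_contacts,
    persistence_network,
    salt_bridge_report,
)
from trajscape.model_io import AtomIndexSet, Ensemble, select
from trajscape.synthetic import OccupancySchedule, make_bundle, make_interaction_ensemble

from conftest import build_structure, static_ensemble


def ser_pair(distance):
    """Two serine residues whose OG atoms sit `distance` Å apart."""
    return build_structure([
        ("CA", "C", "SER", 1, (0, 0, 0)),
        ("CB", "C", "SER", 1, (1.5, 0, 0)),
        ("OG", "O", "SER", 1, (2.9, 0, 0)),
        ("CA", "C", "SER", 2, (2.9 + distance + 2.9, 0, 0)),
        ("CB", "C", "SER", 2, (2.9 + distance + 1.5, 0, 0)),
        ("OG", "O", "SER", 2, (2.9 + distance, 0, 0)),
    ])


def whole(st):
    return select(st, "all")


def classes(edges):
    return {e[2] for e in edges}


def test_polar_edge_below_cutoff():
    st = ser_pair(2.9)
    ens = static_ensemble(st)
    edges = frame_contacts(ens, 0, whole(st), whole(st))
    assert ("A", 1, "SER") in {e[0] for e in edges}
    assert "polar" in classes(edges)


def test_boundary_is_strict():
    # exactly at the cutoff -> no polar edge (the criterion is d < 3.0)
    st = ser_pair(3.0)
    ens = static_ensemble(st)
    edges = frame_contacts(ens, 0, whole(st), whole(st))
    assert "polar" not in classes(edges)


def test_nonpolar_only_when_carbons_close():
    # sidechain C...C at 4.7 (< 4.8) but O...O at 8.3: nonpolar edge only
    st = build_structure([
        ("CA", "C", "SER", 1, (0, 1.4, 0)),
        ("CB", "C", "SER", 1, (0, 0, 0)),
        ("OG", "O", "SER", 1, (-1.8, 0, 0)),
        ("CA", "C", "SER", 2, (4.7, 1.4, 0)),
        ("CB", "C", "SER", 2, (4.7, 0, 0)),
        ("OG", "O", "SER", 2, (6.5, 0, 0)),
    ])
    edges = frame_contacts(static_ensemble(st), 0, whole(st), whole(st))
    assert classes(edges) == {"nonpolar"}


def test_backbone_excluded_in_sidechain_scope():
    # only backbone carbonyl O atoms are close; sidechain-only scope must
    # ignore them, include-backbone must count them
    st = build_structure([
        ("CA", "C", "ALA", 1, (0, 6, 0)),
        ("O", "O", "ALA", 1, (0, 0, 0)),
        ("CA", "C", "ALA", 2, (2.5, 6, 0)),
        ("O", "O", "ALA", 2, (2.5, 0, 0)),
    ])
    ens = static_ensemble(st)
    assert frame_contacts(ens, 0, whole(st), whole(st)) == []
    edges = frame_contacts(ens, 0, whole(st), whole(st),
                           InteractionParams(scope="include-backbone"))
    assert classes(edges) == {"polar"}


def test_ligand_halogen_counts_as_polar():
    st = build_structure([
        ("CA", "C", "SER", 1, (0, 9, 0)),
        ("OG", "O", "SER", 1, (0, 0, 0)),
        ("C1", "C", "LIG", 9, (2.8, 9, 0), True),
        ("CL1", "CL", "LIG", 9, (2.8, 0, 0), True),
    ])
    ens = static_ensemble(st)
    prot = select(st, "not hetero")
    lig = select(st, "hetero")
    with_hal = frame_contacts(ens, 0, prot, lig)
    assert classes(with_hal) == {"polar"}
    without = frame_contacts(ens, 0, prot, lig,
                             InteractionParams(treat_halogens_as_polar=False))
    assert without == []


def test_distance_only_no_angle_term():
    # a geometrically terrible H-bond (donor-acceptor-donor angle irrelevant)
    # still counts at 2.9 Å: the criterion is distance only
    st = build_structure([
        ("CA", "C", "SER", 1, (0, 8, 0)),
        ("OG", "O", "SER", 1, (0, 0, 0)),
        ("CA", "C", "SER", 2, (2.9, 8.0, 0)),
        ("OG", "O", "SER", 2, (2.05, 2.05, 0)),  # ~2.9 Å away, orthogonal approach
    ])
    edges = frame_contacts(static_ensemble(st), 0, whole(st), whole(st))
    assert "polar" in classes(edges)


def brute_force_frame_contacts(structure, frame, params):
    """All-pairs double-loop oracle over residue pairs."""
    from trajscape.interactions import _carbon_atoms, _polar_atoms

    found = set()
    for a in range(structure.n_residues):
        for b in range(a + 1, structure.n_residues):
            for cls, atoms_fn, cutoff in (
                ("polar", _polar_atoms, params.polar_cutoff),
                ("nonpolar", _carbon_atoms, params.nonpolar_cutoff),
            ):
                ia, ib = atoms_fn(structure, a, params), atoms_fn(structure, b, params)
                best = min((np.linalg.norm(frame[i] - frame[j]) for i in ia for j in ib),
                           default=np.inf)
                if best < cutoff:
                    found.add((structure.residue_keys[a], structure.residue_keys[b], cls))
    return found


def test_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    spec = []
    for r in range(8):
        base = rng.uniform(0, 12, 3)
        spec.append(("CA", "C", "SER", r + 1, base))
        spec.append(("CB", "C", "SER", r + 1, base + rng.normal(0, 1, 3)))
        spec.append(("OG", "O", "SER", r + 1, base + rng.normal(0, 1, 3)))
    st = build_structure(spec)
    ens = static_ensemble(st)
    params = InteractionParams()
    got = {(e[0], e[1], e[2]) for e in frame_contacts(ens, 0, whole(st), whole(st), params)}
    assert got == brute_force_frame_contacts(st, st.coordinates, params)


def test_persistence_matches_planted_occupancy(bundle):
    # donor = backbone O of residue 1, acceptor = backbone N of residue 21
    sch = OccupancySchedule(donor_atom=3, acceptor_atom=100, occupancy=0.4)
    ens = make_interaction_ensemble(bundle, sch, 100, seed=5)
    params = InteractionParams(scope="include-backbone")
    net = persistence_network(
        ens, [(AtomIndexSet(np.array([3])), AtomIndexSet(np.array([100])))], params)
    polar = [e for e in net.edges if e.interaction_class == "polar"]
    assert len(polar) == 1
    assert polar[0].persistence == 0.40
    assert polar[0].mean_min_distance == pytest.approx(2.8, abs=1e-9)


def test_full_occupancy_gives_unit_persistence(bundle):
    sch = OccupancySchedule(donor_atom=3, acceptor_atom=100, occupancy=1.0)
    ens = make_interaction_ensemble(bundle, sch, 50, seed=0)
    net = persistence_network(
        ens, [(AtomIndexSet(np.array([3])), AtomIndexSet(np.array([100])))],
        InteractionParams(scope="include-backbone"))
    assert [e.persistence for e in net.edges if e.interaction_class == "polar"] == [1.0]


def test_two_planted_pairs_are_independent_and_exact(bundle):
    schedules = [
        OccupancySchedule(donor_atom=3, acceptor_atom=100, occupancy=0.25),
        OccupancySchedule(donor_atom=8, acceptor_atom=150, occupancy=0.75),
    ]
    ens = make_interaction_ensemble(bundle, schedules, 80, seed=7)
    params = InteractionParams(scope="include-backbone")
    net = persistence_network(
        ens,
        [(AtomIndexSet(np.array([3])), AtomIndexSet(np.array([100]))),
         (AtomIndexSet(np.array([8])), AtomIndexSet(np.array([150])))],
        params)
    polar = sorted((e for e in net.edges if e.interaction_class == "polar"),
                   key=lambda e: e.persistence)
    assert [e.persistence for e in polar] == [0.25, 0.75]


def test_persistence_frame_order_invariance_and_concatenation(bundle):
    sch = OccupancySchedule(donor_atom=3, acceptor_atom=100, occupancy=0.5)
    ens = make_interaction_ensemble(bundle, sch, 40, seed=9)
    params = InteractionParams(scope="include-backbone")
    pair = [(AtomIndexSet(np.array([3])), AtomIndexSet(np.array([100])))]
    p0 = persistence_network(ens, pair, params).edges[0].persistence
    rng = np.random.default_rng(0)
    shuffled = Ensemble(bundle, ens.frames[rng.permutation(40)], burn_in_fraction=0.0)
    assert persistence_network(shuffled, pair, params).edges[0].persistence == p0
    # concatenation: persistence over A+B is the frame-weighted mean
    ens_b = make_interaction_ensemble(bundle, OccupancySchedule(3, 100, 1.0), 20, seed=1)
    pooled = ens.concatenate(ens_b)
    p_pool = persistence_network(pooled, pair, params).edges[0].persistence
    assert p_pool == pytest.approx((40 * 0.5 + 20 * 1.0) / 60, abs=1e-12)


def test_symmetry_of_group_order():
    st = ser_pair(2.5)
    ens = static_ensemble(st)
    g1, g2 = select(st, "resid 1"), select(st, "resid 2")
    e_ab = frame_contacts(ens, 0, g1, g2)
    e_ba = frame_contacts(ens, 0, g2, g1)
    assert {(e[0], e[1], e[2]) for e in e_ab} == {(e[0], e[1], e[2]) for e in e_ba}


def test_unknown_residue_template_warns_and_skips(caplog):
    st = build_structure([
        ("CA", "C", "XYZ", 1, (0, 0, 0)),
        ("OX", "O", "XYZ", 1, (1, 0, 0)),
        ("CA", "C", "SER", 2, (2.0, 0, 0)),
        ("OG", "O", "SER", 2, (2.5, 0, 0)),
    ])
    import logging

    with caplog.at_level(logging.WARNING):
        edges = frame_contacts(static_ensemble(st), 0, whole(st), whole(st))
    assert "polar" not in classes(edges)
    assert any("XYZ" in r.message for r in caplog.records)


class TestSaltBridge:
    @staticmethod
    def asp_arg(distances):
        """ASP-ARG pair whose OD1–NH1 distance follows `distances` per frame."""
        st = build_structure([
            ("CA", "C", "ASP", 10, (0, 5, 0)),
            ("OD1", "O", "ASP", 10, (0, 0, 0)),
            ("OD2", "O", "ASP", 10, (0, -1.2, 0)),
            ("CA", "C", "ARG", 20, (10, 5, 0)),
            ("NH1", "N", "ARG", 20, (10, 0, 0)),
            ("NE", "N", "ARG", 20, (11, 0, 0)),
        ])
        frames = np.repeat(st.coordinates[None], len(distances), axis=0)
        for t, d in enumerate(distances):
            frames[t, 4] = [d, 0, 0]  # NH1 relative to OD1 at origin
        return st, Ensemble(st, frames, burn_in_fraction=0.0)

    def test_always_bonded(self):
        st, ens = self.asp_arg([2.8] * 6)
        rep = salt_bridge_report(ens, [(("A", 10), ("A", 20))])
        assert rep.persistence.tolist() == [1.0]

    def test_alternating_half(self):
        st, ens = self.asp_arg([2.8, 6.0] * 5)
        rep = salt_bridge_report(ens, [(("A", 10), ("A", 20))])
        assert rep.persistence.tolist() == [0.5]

    def test_never_bonded_still_reported(self):
        st, ens = self.asp_arg([6.0] * 4)
        rep = salt_bridge_report(ens, [(("A", 20), ("A", 10))])  # order-insensitive
        assert len(rep) == 1
        assert rep.persistence.tolist() == [0.0]

    def test_missing_residue_listed(self):
        st, ens = self.asp_arg([2.8])
        with pytest.raises(ValueError, match="99"):
            salt_bridge_report(ens, [(("A", 10), ("A", 99))])

    def test_non_charged_pair_rejected(self):
        st = build_structure([
            ("CA", "C", "SER", 1, (0, 0, 0)), ("OG", "O", "SER", 1, (1, 0, 0)),
            ("CA", "C", "ALA", 2, (3, 0, 0)), ("CB", "C", "ALA", 2, (4, 0, 0)),
        ])
        with pytest.raises(ValueError, match="acidic/basic"):
            salt_bridge_report(static_ensemble(st, 2), [(("A", 1), ("A", 2))])


def test_network_invariants():
    e = InteractionEdge(("A", 1, "SER"), ("A", 2, "SER"), "polar", 0.5, 2.8)
    with pytest.raises(ValueError, match="duplicate"):
        InteractionNetwork([e, e], n_frames_analyzed=10)
    with pytest.raises(ValueError, match="persistence"):
        InteractionEdge(("A", 1, "SER"), ("A", 2, "SER"), "polar", 1.5, 2.8)
    with pytest.raises(ValueError, match="distinct"):
        InteractionEdge(("A", 1, "SER"), ("A", 1, "SER"), "polar", 0.5, 2.8)
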