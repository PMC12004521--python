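"""Interaction detection, occurrence networks, and network comparison."""

import dataclasses

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodyn.core import RegionSelection, Trajectory
from haplodyn import network as N
from haplodyn.synthetic import PlantedContact, SyntheticSpec, gen_helix_coil_trajectory


def atoms_traj(coords, resids, resnames, names, elements, **kw):
    return Trajectory(np.asarray(coords, float)[None], resids, resnames, names,
                      elements, **kw)


class TestContactWeight:
    def test_plateau_and_cutoff(self):
        p = N.ContactParams()
        assert N.contact_weight(3.0, p) == 1.0
        assert N.contact_weight(6.0, p) == 0.0
        assert N.contact_weight(4.5, p) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=10.0),
           st.floats(min_value=0.0, max_value=10.0))
    def test_monotone_and_bounded(self, d1, d2):
        p = N.ContactParams()
        w1, w2 = N.contact_weight(d1, p), N.contact_weight(d2, p)
        assert 0.0 <= w1 <= 1.0
        if d1 < d2:
            assert w1 >= w2

    def test_continuity_at_cutoffs(self):
        p = N.ContactParams()
        eps = 1e-9
        assert N.contact_weight(4.0 + eps, p) == pytest.approx(1.0, abs=1e-6)
        assert N.contact_weight(5.0 - eps, p) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_cutoff_order_rejected(self):
        with pytest.raises(ValueError):
            N.ContactParams(inner_cutoff=5.0, outer_cutoff=4.0)


class TestDnaContactMap:
    def _traj(self, protein_xyz, dna_xyz):
        coords = list(protein_xyz) + list(dna_xyz)
        n_p, n_d = len(protein_xyz), len(dna_xyz)
        return atoms_traj(
            coords,
            resids=[10] * n_p + [100 + i for i in range(n_d)],
            resnames=["ALA"] * n_p + ["DA"] * n_d,
            names=[f"C{i}" for i in range(n_p)] + ["P"] * n_d,
            elements=["C"] * n_p + ["P"] * n_d,
        )

    def test_single_close_pair(self):
        t = self._traj([[0, 0, 0]], [[3.0, 0, 0], [30.0, 0, 0]])
        m = N.dna_contact_map(t, 0, RegionSelection(((10, 10),), None),
                              RegionSelection(((100, 101),), None))
        assert m.loc[10, 100] == 1 and m.loc[10, 101] == 0

    def test_three_pairs_sum(self):
        t = self._traj([[0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]], [[0, 3.0, 0]])
        m = N.dna_contact_map(t, 0, RegionSelection(((10, 10),), None),
                              RegionSelection(((100, 100),), None))
        assert m.loc[10, 100] == 3

    def test_all_distant_zero_matrix(self):
        t = self._traj([[0, 0, 0]], [[10.0, 0, 0]])
        m = N.dna_contact_map(t, 0, RegionSelection(((10, 10),), None),
                              RegionSelection(((100, 100),), None))
        assert (np.asarray(m) == 0).all()


class TestDetectEdges:
    def test_salt_bridge_within_cutoff(self):
        t = atoms_traj([[0, 0, 0], [4.0, 0, 0]], [1, 5], ["ARG", "ASP"],
                       ["NH1", "OD1"], ["N", "O"])
        assert N.detect_edges(t, 0, "salt-bridge") == {(1, 5)}

    def test_salt_bridge_beyond_cutoff_absent(self):
        t = atoms_traj([[0, 0, 0], [4.6, 0, 0]], [1, 5], ["ARG", "ASP"],
                       ["NH1", "OD1"], ["N", "O"])
        assert N.detect_edges(t, 0, "salt-bridge") == set()

    def test_adjacent_residues_never_edges(self):
        t = atoms_traj([[0, 0, 0], [3.0, 0, 0]], [4, 5], ["ARG", "ASP"],
                       ["NH1", "OD1"], ["N", "O"])
        assert N.detect_edges(t, 0, "salt-bridge") == set()

    def test_glycine_chain_has_no_hydrophobic_edges(self):
        t = atoms_traj([[0, 0, 0], [3.0, 0, 0]], [1, 4], ["GLY", "GLY"],
                       ["CA", "CA"], ["C", "C"])
        assert N.detect_edges(t, 0, "hydrophobic") == set()

    def test_apolar_sidechains_within_cutoff(self):
        t = atoms_traj([[0, 0, 0], [3.0, 0, 0]], [1, 4], ["LEU", "VAL"],
                       ["CB", "CB"], ["C", "C"])
        assert N.detect_edges(t, 0, "hydrophobic") == {(1, 4)}

    def test_hydrogen_bond_geometry(self):
        # linear N-H...O at 2.9 A donor-acceptor
        t = atoms_traj([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]],
                       [1, 1, 5], ["ALA", "ALA", "SER"], ["N", "H", "O"],
                       ["N", "H", "O"])
        assert N.detect_edges(t, 0, "hydrogen-bond") == {(1, 5)}

    def test_bent_hydrogen_bond_rejected(self):
        # donor-H-acceptor angle 90 deg < 120 deg
        t = atoms_traj([[0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]],
                       [1, 1, 5], ["ALA", "ALA", "SER"], ["N", "H", "O"],
                       ["N", "H", "O"])
        assert N.detect_edges(t, 0, "hydrogen-bond") == set()

    def test_unknown_type_rejected(self, ideal_helix):
        with pytest.raises(TypeError):
            N.detect_edges(ideal_helix, 0, "pi-stacking")


class TestOccurrenceNetwork:
    def _alternating(self):
        # LEU CB pair alternating between 3 A and 9 A
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = [3.0, 9.0, 3.0, 9.0]
        return Trajectory(coords, [1, 4], ["LEU", "LEU"], ["CB", "CB"],
                          ["C", "C"], frame_interval_ps=100.0)

    def test_persistent_contact_occurrence_one(self):
        t = self._alternating()
        t.coordinates[:, 1, 0] = 3.0
        g = N.occurrence_network(t, "hydrophobic",
                                 N.ContactParams(network_stride_ps=100))
        assert g[1][4]["occurrence"] == 1.0

    def test_alternating_contact_occurrence_half(self):
        g = N.occurrence_network(self._alternating(), "hydrophobic",
                                 N.ContactParams(network_stride_ps=100))
        assert g[1][4]["occurrence"] == 0.5

    def test_frame_order_permutation_invariant(self):
        t = self._alternating()
        perm = dataclasses.replace(t, coordinates=t.coordinates[[2, 0, 3, 1]])
        p = N.ContactParams(network_stride_ps=100)
        g1 = N.occurrence_network(t, "hydrophobic", p)
        g2 = N.occurrence_network(perm, "hydrophobic", p)
        assert nx.utils.graphs_equal(g1, g2)

    def test_planted_occurrence_recovered(self):
        pc = PlantedContact(pair=((2, "CA"), (10, "CA")), occurrence=0.705,
                            contact_distance=4.0, open_distance=9.0)
        spec = SyntheticSpec(seed=3, n_frames=10_000, n_residues=12,
                             planted_contacts=(pc,))
        traj = gen_helix_coil_trajectory(spec)
        occ = N.pair_distance_occurrence(traj, ((2, "CA"), (10, "CA")), 4.5)
        se = np.sqrt(0.705 * 0.295 / spec.n_frames)
        assert abs(occ - 0.705) < 3 * se


class TestCombineBinarize:
    def _net(self, edges):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3, 4])
        for (i, j), w in edges.items():
            g.add_edge(i, j, occurrence=w, interaction="x")
        return g

    def test_max_across_types(self):
        nets = [self._net({(1, 2): w}) for w in (0.3, 0.5, 0.2)]
        combined = N.combine_max(nets)
        assert combined[1][2]["occurrence"] == 0.5

    def test_edge_in_one_network_preserved(self):
        combined = N.combine_max([self._net({(1, 2): 0.7}), self._net({})])
        assert combined[1][2]["occurrence"] == 0.7

    def test_idempotent(self):
        g = self._net({(1, 2): 0.4, (3, 4): 0.9})
        combined = N.combine_max([g, g, g])
        assert nx.utils.graphs_equal(
            N.binarize(combined, 0.0), N.binarize(g, 0.0))
        for i, j in g.edges:
            assert combined[i][j]["occurrence"] == g[i][j]["occurrence"]

    def test_combined_weight_dominates_components(self):
        nets = [self._net({(1, 2): 0.3, (2, 3): 0.1}),
                self._net({(1, 2): 0.6})]
        combined = N.combine_max(nets)
        for g in nets:
            for i, j, d in g.edges(data=True):
                assert combined[i][j]["occurrence"] >= d["occurrence"]

    def test_node_set_mismatch_rejected(self):
        g1, g2 = self._net({}), self._net({})
        g2.add_node(99)
        with pytest.raises(ValueError):
            N.combine_max([g1, g2])

    def test_binarize_strict_threshold(self):
        g = self._net({(1, 2): 0.19, (1, 3): 0.20, (1, 4): 0.21})
        b = N.binarize(g, 0.2)
        assert set(b.edges) == {(1, 4)}

    def test_binarize_zero_cutoff_keeps_positive(self):
        g = self._net({(1, 2): 0.05, (3, 4): 0.99})
        assert b_edges(N.binarize(g, 0.0)) == {(1, 2), (3, 4)}


def b_edges(g):
    return {tuple(sorted(e)) for e in g.edges}


class TestJaccard:
    def _g(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return g

    def test_identical_graphs(self):
        g = self._g([(1, 2), (2, 3)])
        assert N.jaccard(g, g) == 1.0

    def test_disjoint_edge_sets(self):
        assert N.jaccard(self._g([(1, 2)]), self._g([(3, 4)])) == 0.0

    def test_hand_example_half(self):
        g1 = self._g([("a", "x"), ("b", "x"), ("c", "x")])
        g2 = self._g([("b", "x"), ("c", "x"), ("d", "x")])
        assert N.jaccard(g1, g2) == 0.5

    def test_both_empty_defined_as_one(self):
        assert N.jaccard(nx.Graph(), nx.Graph()) == 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e1 = {(int(a), int(b)) for a, b in rng.integers(0, 8, (6, 2)) if a != b}
            e2 = {(int(a), int(b)) for a, b in rng.integers(0, 8, (6, 2)) if a != b}
            g1, g2 = self._g(e1), self._g(e2)
            j = N.jaccard(g1, g2)
            assert 0.0 <= j <= 1.0
            assert j == N.jaccard(g2, g1)
            if b_edges(g1) == b_edges(g2):
                assert j == 1.0


class TestOccurrenceDifference:
    def _net(self, edges):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        for (i, j), w in edges.items():
            g.add_edge(i, j, occurrence=w)
        return g

    def test_identical_networks_all_zero(self):
        g = self._net({(1, 2): 0.5})
        d = N.occurrence_difference(g, g, focus_nodes=None)
        assert all(v == 0.0 for v in d.values())

    def test_missing_edge_counts_zero(self):
        d = N.occurrence_difference(self._net({(1, 2): 0.7}), self._net({}),
                                    focus_nodes=[1])
        assert d[(1, 2)] == pytest.approx(0.7)

    def test_antisymmetry(self):
        a = self._net({(1, 2): 0.7, (2, 3): 0.1})
        b = self._net({(1, 2): 0.4})
        dab = N.occurrence_difference(a, b, focus_nodes=[2])
        dba = N.occurrence_difference(b, a, focus_nodes=[2])
        assert dab == {k: pytest.approx(-v) for k, v in dba.items()}


class TestPairDistanceOccurrence:
    def test_always_below_threshold(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 3.0
        t = Trajectory(coords, [1, 5], ["ALA", "ALA"], ["CA", "CA"], ["C", "C"])
        assert N.pair_distance_occurrence(t, ((1, "CA"), (5, "CA")), 4.5) == 1.0

    def test_unresolvable_atom_rejected(self, ideal_helix):
        from haplodyn.core import TopologyError
        with pytest.raises(TopologyError):
            N.pair_distance_occurrence(ideal_helix, ((1, "XX"), (5, "CA")), 4.5)
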