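"""Single-linkage distance-cutoff clustering under slab PBC."""

import numpy as np
import pytest

from samsurf.clustering import (
    ClusterParams,
    brute_force_cluster_frame,
    cluster_frame,
    cluster_size_distribution,
    ion_moiety_clusters,
    partitions_equal,
)
from samsurf.synthetic_surface import plant_clusters
from samsurf.traj_io import BoxSpec, Frame

from conftest import make_topology


def frame_of(positions, box):
    return Frame(time=0.0, positions=np.asarray(positions, dtype=float), box=box)


def random_instance(rng, n_molecules=60, atoms_per_mol=2, box=BoxSpec(30, 30, 15)):
    pos = rng.uniform(0, [box.lx, box.ly, box.lz], size=(n_molecules * atoms_per_mol, 3))
    topo = make_topology(
        ["phenyl_C"] * (n_molecules * atoms_per_mol),
        molecule_id=np.repeat(np.arange(n_molecules), atoms_per_mol),
    )
    return frame_of(pos, box), topo


class TestClusterFrame:
    box = BoxSpec(50.0, 50.0, 20.0)

    def test_boundary_is_exclusive(self):
        """Closest inter-molecule distance 4.1 A at cutoff 4 A: two singletons."""
        topo = make_topology(["phenyl_C", "phenyl_C"], molecule_id=[0, 1])
        f = frame_of([[10, 10, 5], [14.1, 10, 5]], self.box)
        part = cluster_frame(f, topo, ClusterParams(cutoff=4.0))
        assert sorted(part.sizes) == [1, 1]

    def test_exact_cutoff_does_not_link(self):
        topo = make_topology(["phenyl_C", "phenyl_C"], molecule_id=[0, 1])
        f = frame_of([[10, 10, 5], [14.0, 10, 5]], self.box)
        part = cluster_frame(f, topo, ClusterParams(cutoff=4.0))
        assert sorted(part.sizes) == [1, 1]

    def test_transitive_chain(self):
        """A-B and B-C at 3.9 A, A-C at 7.8 A: one cluster of three."""
        topo = make_topology(["phenyl_C"] * 3, molecule_id=[0, 1, 2])
        f = frame_of([[10, 10, 5], [13.9, 10, 5], [17.8, 10, 5]], self.box)
        part = cluster_frame(f, topo, ClusterParams(cutoff=4.0))
        assert [len(c) for c in part.clusters] == [3]

    def test_periodic_wrap_links_across_boundary(self):
        topo = make_topology(["phenyl_C", "phenyl_C"], molecule_id=[0, 1])
        f = frame_of([[0.5, 10, 5], [self.box.lx - 0.5, 10, 5]], self.box)
        part = cluster_frame(f, topo, ClusterParams(cutoff=2.0))
        assert [len(c) for c in part.clusters] == [2]

    def test_z_not_periodic(self):
        box = BoxSpec(50.0, 50.0, 10.0)
        topo = make_topology(["phenyl_C", "phenyl_C"], molecule_id=[0, 1])
        f = frame_of([[10, 10, 0.5], [10, 10, 9.5]], box)
        part = cluster_frame(f, topo, ClusterParams(cutoff=2.0))
        assert sorted(part.sizes) == [1, 1]

    def test_cutoff_beyond_minimum_image_rejected(self):
        topo = make_topology(["phenyl_C"], molecule_id=[0])
        f = frame_of([[1, 1, 1]], BoxSpec(10, 10, 10))
        with pytest.raises(ValueError, match="minimum-image"):
            cluster_frame(f, topo, ClusterParams(cutoff=5.0))

    def test_oracle_equivalence_random_instances(self, rng):
        """Cell-list/union-find partition equals all-pairs BFS on random
        periodic configurations."""
        params = ClusterParams(cutoff=4.0)
        for _ in range(25):
            f, topo = random_instance(rng)
            fast = cluster_frame(f, topo, params)
            slow = brute_force_cluster_frame(f, topo, params)
            assert partitions_equal(fast, slow)

    def test_monotone_refinement_in_cutoff(self, rng):
        """Every cluster at a smaller cutoff is contained in one cluster at
        a larger cutoff."""
        f, topo = random_instance(rng)
        small = cluster_frame(f, topo, ClusterParams(cutoff=3.0))
        large = cluster_frame(f, topo, ClusterParams(cutoff=6.0))
        for c1 in small.clusters:
            assert any(c1 <= c2 for c2 in large.clusters)

    def test_tiny_cutoff_gives_singletons(self, rng):
        f, topo = random_instance(rng)
        part = cluster_frame(f, topo, ClusterParams(cutoff=1e-6))
        assert all(s == 1 for s in part.sizes)

    def test_permutation_invariance(self, rng):
        f, topo = random_instance(rng)
        params = ClusterParams(cutoff=4.0)
        ref = sorted(cluster_frame(f, topo, params).sizes)
        perm = rng.permutation(topo.n_atoms)
        topo2 = make_topology(
            list(topo.roles[perm]), molecule_id=topo.molecule_id[perm]
        )
        f2 = frame_of(f.positions[perm], f.box)
        assert sorted(cluster_frame(f2, topo2, params).sizes) == ref


class TestSizeDistribution:
    def test_all_singletons(self):
        from samsurf.clustering import ClusterPartition

        parts = [ClusterPartition(0, [{1}, {2}, {3}])]
        dist = cluster_size_distribution(parts)
        assert dist.probabilities == {1: 1.0}
        assert dist.mean_size == 1.0

    def test_hand_counted_mixture(self):
        """Clusters {3,3,2}: P(2)=1/3, P(3)=2/3, mean 8/3."""
        from samsurf.clustering import ClusterPartition

        parts = [ClusterPartition(0, [{1, 2, 3}, {4, 5, 6}, {7, 8}])]
        dist = cluster_size_distribution(parts)
        assert dist.probabilities[2] == pytest.approx(1 / 3)
        assert dist.probabilities[3] == pytest.approx(2 / 3)
        assert dist.mean_size == pytest.approx(8 / 3)
        assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_min_size_excludes_before_normalization(self):
        from samsurf.clustering import ClusterPartition

        parts = [ClusterPartition(0, [{1}, {2, 3}, {4, 5}])]
        dist = cluster_size_distribution(parts, min_size=2)
        assert dist.probabilities == {2: 1.0}
        assert dist.n_observations == 2

    def test_empty_after_filtering_rejected(self):
        from samsurf.clustering import ClusterPartition

        with pytest.raises(ValueError, match="min_size"):
            cluster_size_distribution([ClusterPartition(0, [{1}])], min_size=5)


def test_planted_partition_recovered_exactly():
    """Clustering at the planted cutoff returns exactly the planted labels."""
    planted = plant_clusters(
        [4, 3, 3, 2, 1, 1], intra_spread=2.5, inter_separation=7.0,
        box=BoxSpec(90, 90, 20), seed=7, cutoff=4.0, atoms_per_molecule=2,
    )
    f, topo = planted.to_frame_topology()
    part = cluster_frame(f, topo, ClusterParams(cutoff=planted.cutoff))
    recovered = {frozenset(c) for c in part.clusters}
    truth = {
        frozenset(np.flatnonzero(planted.true_labels == lab))
        for lab in set(planted.true_labels)
    }
    assert recovered == truth


class TestIonMoietyClusters:
    box = BoxSpec(50.0, 50.0, 20.0)

    def topo_two_carbs(self):
        return make_topology(
            ["ion", "carboxylate_C", "carboxylate_O", "carboxylate_C", "carboxylate_O"],
            molecule_id=[0, 1, 1, 2, 2],
        )

    def test_ion_bridging_two_carboxylates(self):
        """One ion within cutoff of two carboxylates joins them: (1 ion, 2
        moiety molecules)."""
        f = frame_of(
            [[10, 10, 5], [6.0, 10, 5], [6.0, 10, 6], [14.0, 10, 5], [14.0, 10, 6]],
            self.box,
        )
        part = ion_moiety_clusters(f, self.topo_two_carbs(), cutoff=5.0)
        comps = sorted(part.compositions)
        assert comps == [(1, 2)]

    def test_no_ions_reduces_to_moieties(self):
        topo = make_topology(
            ["carboxylate_C", "carboxylate_O", "carboxylate_C", "carboxylate_O"],
            molecule_id=[1, 1, 2, 2],
        )
        f = frame_of([[6, 10, 5], [6, 10, 6], [30, 10, 5], [30, 10, 6]], self.box)
        part = ion_moiety_clusters(f, topo, cutoff=5.0)
        assert sorted(part.sizes) == [1, 1]
        assert sorted(part.compositions) == [(0, 1), (0, 1)]

    def test_matches_brute_force_on_random_configuration(self, rng):
        n_ions, n_mols = 20, 15
        box = BoxSpec(30, 30, 15)
        roles = ["ion"] * n_ions + ["carboxylate_C"] * n_mols + ["carboxylate_O"] * n_mols
        mol_id = list(range(n_ions)) + list(range(100, 100 + n_mols)) * 2
        topo = make_topology(roles, molecule_id=mol_id)
        pos = rng.uniform(0, [box.lx, box.ly, box.lz], size=(topo.n_atoms, 3))
        f = frame_of(pos, box)
        part = ion_moiety_clusters(f, topo, cutoff=5.0)
        # independent check: brute-force pairwise linking over expanded keys
        from samsurf.pbc import minimum_image_distance

        keys = [("ion", i) for i in range(n_ions)] + [
            ("mol", int(m)) for m in (100 + np.arange(n_mols))
        ]
        atom_keys = [("ion", i) for i in range(n_ions)] + [
            ("mol", int(m)) for m in mol_id[n_ions:]
        ]
        d = minimum_image_distance(pos, pos, box)
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(keys)
        n = len(pos)
        for i in range(n):
            for j in range(i + 1, n):
                if atom_keys[i] != atom_keys[j] and d[i, j] < 5.0:
                    g.add_edge(atom_keys[i], atom_keys[j])
        truth = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(c) for c in part.clusters} == truth
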