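"""Network structures, I/O, hierarchic parameter and partitioning."""

import numpy as np
import pytest

from darcyparam.network import (
    InfeasiblePartitionError,
    NetworkValidationError,
    PartitionVector,
    UnsupportedTopologyError,
    Vessel,
    VesselNode,
    VascularNetwork,
    compute_zeta,
    default_partition_targets,
    optimise_partition,
    partition_by_zeta,
    read_network,
    write_network,
)
from darcyparam.synthetic import GeneratorConfig, generate_volume_filling_tree

from conftest import make_network, random_tree


class TestConstruction:
    def test_two_node_vessel_geometry(self):
        net = make_network([(0, 0, 0), (1, 0, 0)], [0.001, 0.001], [(0, 1)])
        assert net.n_vessels == 1
        v = net.vessels[0]
        assert v.length == pytest.approx(1.0)
        assert v.radius == pytest.approx(0.001)
        assert v.volume == pytest.approx(np.pi * 0.001**2 * 1.0)

    def test_dangling_edge_reference_rejected(self):
        nodes = [VesselNode(0, np.zeros(3), 0.001), VesselNode(1, np.ones(3), 0.001)]
        with pytest.raises(NetworkValidationError, match="missing node"):
            VascularNetwork(nodes, [Vessel(0, 0, 5)])

    def test_non_positive_radius_rejected(self):
        with pytest.raises(NetworkValidationError, match="radius"):
            VesselNode(0, np.zeros(3), 0.0)

    def test_disconnected_rejected(self):
        nodes = [VesselNode(i, np.array([i, 0, 0.0]), 0.001) for i in range(4)]
        with pytest.raises(NetworkValidationError, match="connected"):
            VascularNetwork(nodes, [Vessel(0, 0, 1), Vessel(1, 2, 3)])

    def test_node_kinds(self, y_network):
        kinds = {nid: n.kind for nid, n in y_network.nodes.items()}
        assert kinds == {0: "root", 1: "internal", 2: "terminal", 3: "terminal"}


class TestIO:
    def test_round_trip(self, tmp_path):
        net = generate_volume_filling_tree(GeneratorConfig(levels=4, seed=3))
        for v in net.vessels.values():
            v.compartment = 1 + v.id % 3
        write_network(net, tmp_path)
        back = read_network(tmp_path)
        assert back.n_nodes == net.n_nodes
        assert back.n_vessels == net.n_vessels
        assert back.root_id == net.root_id
        for nid in net.nodes:
            np.testing.assert_array_equal(
                back.nodes[nid].position, net.nodes[nid].position
            )
            assert back.nodes[nid].radius == net.nodes[nid].radius
        for vid in net.vessels:
            assert back.vessels[vid].node_a == net.vessels[vid].node_a
            assert back.vessels[vid].node_b == net.vessels[vid].node_b
            assert back.vessels[vid].compartment == net.vessels[vid].compartment
            assert back.vessels[vid].flux == net.vessels[vid].flux
            assert back.vessels[vid].radius == pytest.approx(
                net.vessels[vid].radius, rel=1e-15
            )

    def test_write_counts_y_network(self, tmp_path, y_network):
        write_network(y_network, tmp_path)
        nodes = (tmp_path / "nodes.csv").read_text().strip().splitlines()
        edges = (tmp_path / "edges.csv").read_text().strip().splitlines()
        assert len(nodes) == 1 + 4 and len(edges) == 1 + 3

    def test_empty_network_refused(self, tmp_path):
        net = make_network([(0, 0, 0)], [0.001], [])
        with pytest.raises(NetworkValidationError):
            write_network(net, tmp_path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_network(tmp_path)


def brute_force_zeta(net):
    """Independent recursive distal-length accumulation."""
    total = sum(v.length for v in net.vessels.values())

    def distal(nid):
        s = 0.0
        for vid in net.outgoing(nid):
            v = net.vessels[vid]
            s += v.length + distal(v.node_b)
        return s

    return {nid: distal(nid) / total for nid in net.nodes}


class TestZeta:
    def test_single_vessel_endpoints(self):
        net = make_network([(0, 0, 0), (0, 0, 2.0)], [0.001, 0.001], [(0, 1)])
        h = compute_zeta(net)
        assert h.zeta_node[0] == 1.0
        assert h.zeta_node[1] == 0.0
        assert h.zeta_vessel[0] == 0.5

    def test_symmetric_y_junction(self, y_network):
        h = compute_zeta(y_network)
        assert h.zeta_node[1] == pytest.approx(2.0 / 3.0)
        assert h.zeta_node[0] == 1.0
        assert h.zeta_node[2] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_recursive_oracle(self, seed):
        net = random_tree(seed)
        h = compute_zeta(net)
        ref = brute_force_zeta(net)
        for nid, z in ref.items():
            assert h.zeta_node[nid] == pytest.approx(z, abs=1e-13)
        for vid, v in net.vessels.items():
            zb = 0.5 * (ref[v.node_a] + ref[v.node_b])
            assert h.zeta_vessel[vid] == pytest.approx(zb, abs=1e-13)

    def test_monotone_along_vessels(self, small_random_tree):
        h = compute_zeta(small_random_tree)
        for v in small_random_tree.vessels.values():
            assert h.zeta_node[v.node_a] > h.zeta_node[v.node_b]

    def test_cycle_rejected(self):
        positions = [(0, 0, 0), (1, 0, 0), (1, 1, 0)]
        net = make_network(positions, [0.001] * 3, [(0, 1), (1, 2), (2, 0)], root_id=0)
        with pytest.raises(UnsupportedTopologyError):
            compute_zeta(net)


class TestPartition:
    def test_single_interval_covers_everything(self, small_random_tree):
        h = compute_zeta(small_random_tree)
        labels = partition_by_zeta(
            small_random_tree, h, PartitionVector(np.array([1.0, 0.0]))
        )
        assert set(labels.values()) == {1}

    def test_boundary_convention(self):
        Z = PartitionVector(np.array([1.0, 0.5, 0.0]))
        from darcyparam.network import _labels_for_z

        labels = _labels_for_z(np.array([0.5, 0.49, 1.0, 0.0]), Z.Z)
        assert list(labels) == [1, 2, 1, 2]

    def test_partition_vector_validation(self):
        with pytest.raises(ValueError):
            PartitionVector(np.array([1.0, 0.5, 0.6, 0.0]))
        with pytest.raises(ValueError):
            PartitionVector(np.array([0.9, 0.0]))

    def test_total_disjoint_cover_random_Z(self, small_random_tree):
        h = compute_zeta(small_random_tree)
        rng = np.random.default_rng(11)
        for _ in range(10):
            interior = np.sort(rng.uniform(0, 1, size=2))[::-1]
            Z = PartitionVector(np.array([1.0, *interior, 0.0]))
            labels = partition_by_zeta(small_random_tree, h, Z)
            assert set(labels) == set(small_random_tree.vessels)
            assert all(1 <= l <= 3 for l in labels.values())

    def test_permutation_invariance(self):
        net = random_tree(5)
        h = compute_zeta(net)
        Z = PartitionVector(np.array([1.0, 0.4, 0.0]))
        labels = partition_by_zeta(net, h, Z)
        # re-index nodes and vessels by a permutation and rebuild
        rng = np.random.default_rng(0)
        nperm = {nid: int(p) for nid, p in zip(sorted(net.nodes), rng.permutation(net.n_nodes))}
        positions = [None] * net.n_nodes
        radii = [None] * net.n_nodes
        for nid, node in net.nodes.items():
            positions[nperm[nid]] = node.position
            radii[nperm[nid]] = node.radius
        edges = [None] * net.n_vessels
        vperm = {vid: int(p) for vid, p in zip(sorted(net.vessels), rng.permutation(net.n_vessels))}
        for vid, v in net.vessels.items():
            edges[vperm[vid]] = (nperm[v.node_a], nperm[v.node_b])
        net2 = make_network(positions, radii, edges, root_id=nperm[net.root_id])
        labels2 = partition_by_zeta(net2, compute_zeta(net2), Z)
        for vid, lab in labels.items():
            assert labels2[vperm[vid]] == lab

    def test_paper_partition_on_deep_tree(self):
        net = generate_volume_filling_tree(GeneratorConfig(levels=15, seed=0))
        h = compute_zeta(net)
        Z = PartitionVector(np.array([1.0, 0.019879, 0.000118, 0.0]))
        partition_by_zeta(net, h, Z)
        means = {}
        for c in (1, 2, 3):
            radii = [v.radius for v in net.vessels.values() if v.compartment == c]
            assert radii, f"compartment {c} is empty"
            means[c] = np.mean(radii)
        assert means[1] > means[2] > means[3]


class TestOptimisePartition:
    def test_single_compartment_trivial(self, small_random_tree):
        h = compute_zeta(small_random_tree)
        Z = optimise_partition(small_random_tree, h, [0.005])
        np.testing.assert_array_equal(Z.Z, [1.0, 0.0])

    def test_two_scale_tree_recovered_exactly(self):
        # proximal chain with radii ~10x the distal chain radii
        positions = [(i, 0, 0.0) for i in range(9)]
        radii = [0.02] * 4 + [0.002] * 5
        edges = [(i, i + 1) for i in range(8)]
        net = make_network(positions, radii, edges)
        h = compute_zeta(net)
        r = net.vessel_array("radius")
        prox = r[:3]  # vessels 0..2 have both endpoints proximal
        # vessel 3 bridges the scales; targets = true block means
        t1 = float(np.mean(r[:4]))
        t2 = float(np.mean(r[4:]))
        Z = optimise_partition(net, h, [t1, t2])
        labels = partition_by_zeta(net, h, Z)
        assert [labels[i] for i in range(8)] == [1] * 4 + [2] * 4

    def test_beats_random_search(self):
        net = generate_volume_filling_tree(GeneratorConfig(levels=8, seed=2))
        h = compute_zeta(net)
        targets = np.array([0.030, 0.006, 0.003])
        Z = optimise_partition(net, h, targets)

        def cost(z1, z2):
            labels = partition_by_zeta(
                net, h, PartitionVector(np.array([1.0, z1, z2, 0.0]))
            )
            sq = 0.0
            for c in (1, 2, 3):
                radii = [net.vessels[v].radius for v, l in labels.items() if l == c]
                if not radii:
                    return np.inf
                sq += (np.mean(radii) - targets[c - 1]) ** 2
            return np.sqrt(sq / 3)

        best = cost(Z.Z[1], Z.Z[2])
        rng = np.random.default_rng(42)
        for _ in range(1000):
            z = np.sort(rng.uniform(0, 1, size=2))[::-1]
            if z[0] <= z[1]:
                continue
            assert best <= cost(*z) + 1e-12

    def test_infeasible_when_too_few_scales(self):
        net = make_network([(0, 0, 0), (1, 0, 0)], [0.001, 0.001], [(0, 1)])
        h = compute_zeta(net)
        with pytest.raises(InfeasiblePartitionError):
            optimise_partition(net, h, [0.03, 0.006, 0.003])

    def test_default_targets_decreasing(self):
        net = generate_volume_filling_tree(GeneratorConfig(levels=6, seed=1))
        t = default_partition_targets(net)
        assert len(t) == 3 and t[0] > t[1] > t[2]
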