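import logging

import numpy as np
import pytest

from darcyparam.network import Vessel, VesselNode, VascularNetwork

logging.getLogger("darcyparam").setLevel(logging.ERROR)
logging.getLogger("darcyparam.rve").setLevel(logging.ERROR)
logging.getLogger("darcyparam.permeability").setLevel(logging.ERROR)


def make_network(positions, radii, edges, root_id=0):
    nodes = [
        VesselNode(i, np.asarray(p, dtype=float), float(r))
        for i, (p, r) in enumerate(zip(positions, radii))
    ]
    vessels = [Vessel(j, a, b) for j, (a, b) in enumerate(edges)]
    return VascularNetwork(nodes, vessels, root_id=root_id)


@pytest.fixture
def y_network():
    """Symmetric Y: root -> junction -> two terminals, all lengths 1."""
    positions = [(0, 0, 0), (1, 0, 0), (2, 0, 0.0), (1.5, 0, 0)]
    # place terminals at distance 1 from the junction
    positions = [(0, 0, 0), (1, 0, 0), (1 + 0.6, 0.8, 0), (1 + 0.6, -0.8, 0)]
    radii = [0.002, 0.002, 0.001, 0.001]
    edges = [(0, 1), (1, 2), (1, 3)]
    return make_network(positions, radii, edges)


def random_tree(seed, max_nodes=60, radius_range=(0.001, 0.01)):
    """Random asymmetric rooted tree with random geometry (seeded)."""
    rng = np.random.default_rng(seed)
    positions = [np.zeros(3)]
    radii = [float(rng.uniform(*radius_range))]
    edges = []
    frontier = [0]
    while frontier and len(positions) < max_nodes:
        nid = frontier.pop(0)
        n_children = rng.choice([0, 2], p=[0.3, 0.7]) if nid else 2
        for _ in range(n_children):
            if len(positions) >= max_nodes:
                break
            child = len(positions)
            positions.append(positions[nid] + rng.normal(scale=0.3, size=3))
            radii.append(float(rng.uniform(*radius_range)))
            edges.append((nid, child))
            frontier.append(child)
    return make_network(positions, radii, edges)


@pytest.fixture
def small_random_tree():
    return random_tree(7)
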