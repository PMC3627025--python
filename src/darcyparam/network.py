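"""Vascular network data structures, file I/O, hierarchy and partitioning.

A vascular network is a collection of nodes (position in mm, radius in mm)
joined by straight vessel segments.  Segments are flow-oriented ``a -> b``.
Synthetic networks are rooted trees; file-supplied networks may be general
connected graphs (e.g. capillary lattices), in which case the tree-only
operations (hierarchic parameter, partitioning) raise
:class:`UnsupportedTopologyError`.

The hierarchic parameter ``zeta`` orders the network from the inlet
(``zeta = 1`` at the root) to the distal terminals (``zeta = 0``): at a node
it is the total length of all vessels distal to that node divided by the
total vessel length of the network.  Compartment partitioning thresholds the
per-vessel average ``zeta`` against an ordered vector ``Z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "VesselNode",
    "Vessel",
    "VascularNetwork",
    "HierarchicField",
    "PartitionVector",
    "NetworkValidationError",
    "UnsupportedTopologyError",
    "InfeasiblePartitionError",
    "read_network",
    "write_network",
    "compute_zeta",
    "partition_by_zeta",
    "optimise_partition",
]


class NetworkValidationError(ValueError):
    """Raised when a network violates structural invariants."""


class UnsupportedTopologyError(NetworkValidationError):
    """Raised for operations that require a rooted tree (e.g. zeta on loops)."""


class InfeasiblePartitionError(ValueError):
    """Raised when a partition into N compartments cannot be realised."""


@dataclass
class VesselNode:
    id: int
    position: np.ndarray  # (3,) mm
    radius: float  # mm
    kind: str = "internal"  # {root, terminal, internal}

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise NetworkValidationError(f"node {self.id}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise NetworkValidationError(f"node {self.id}: non-finite position")
        if not (self.radius > 0):
            raise NetworkValidationError(f"node {self.id}: radius must be > 0")


@dataclass
class Vessel:
    id: int
    node_a: int
    node_b: int
    length: float = 0.0  # mm, Euclidean endpoint distance
    radius: float = 0.0  # mm, mean of endpoint nodal radii
    flux: float = float("nan")  # mm^3 / s, positive a -> b
    compartment: Optional[int] = None  # 1-based label

    @property
    def volume(self) -> float:
        """Lumen volume pi r^2 l in mm^3."""
        return math.pi * self.radius**2 * self.length


class VascularNetwork:
    """Connected vessel network with flow-oriented segments.

    Parameters
    ----------
    nodes, vessels
        Node and vessel lists.  Vessel lengths/radii are (re)computed from
        the nodal data on construction.
    root_id
        Inlet node.  If omitted it is inferred as the unique node with no
        incoming vessel (trees only); general graphs may leave it ``None``.
    """

    def __init__(
        self,
        nodes: Iterable[VesselNode],
        vessels: Iterable[Vessel],
        root_id: Optional[int] = None,
    ) -> None:
        self.nodes: Dict[int, VesselNode] = {n.id: n for n in nodes}
        self.vessels: Dict[int, Vessel] = {v.id: v for v in vessels}
        if not self.nodes:
            raise NetworkValidationError("network has no nodes")
        self.adjacency: Dict[int, List[int]] = {nid: [] for nid in self.nodes}
        for v in self.vessels.values():
            for nid in (v.node_a, v.node_b):
                if nid not in self.nodes:
                    raise NetworkValidationError(
                        f"vessel {v.id} references missing node {nid}"
                    )
            if v.node_a == v.node_b:
                raise NetworkValidationError(f"vessel {v.id} is a self-loop")
            self.adjacency[v.node_a].append(v.id)
            self.adjacency[v.node_b].append(v.id)
        self._recompute_geometry()
        self._validate_connected()
        self.root_id = self._resolve_root(root_id)
        self._mark_node_kinds()

    # -- construction helpers -------------------------------------------------

    def _recompute_geometry(self) -> None:
        for v in self.vessels.values():
            pa = self.nodes[v.node_a].position
            pb = self.nodes[v.node_b].position
            v.length = float(np.linalg.norm(pb - pa))
            if not v.length > 0:
                raise NetworkValidationError(f"vessel {v.id} has zero length")
            v.radius = 0.5 * (self.nodes[v.node_a].radius + self.nodes[v.node_b].radius)

    def _validate_connected(self) -> None:
        g = self.as_graph()
        if self.vessels and not nx.is_connected(g):
            raise NetworkValidationError("network is not connected")

    def _resolve_root(self, root_id: Optional[int]) -> Optional[int]:
        if root_id is not None:
            if root_id not in self.nodes:
                raise NetworkValidationError(f"root node {root_id} not in network")
            return root_id
        has_incoming = {v.node_b for v in self.vessels.values()}
        candidates = [nid for nid in self.nodes if nid not in has_incoming]
        if len(candidates) == 1:
            return candidates[0]
        return None

    def _mark_node_kinds(self) -> None:
        for nid, node in self.nodes.items():
            if nid == self.root_id:
                node.kind = "root"
            elif len(self.adjacency[nid]) == 1:
                node.kind = "terminal"
            else:
                node.kind = "internal"

    # -- queries --------------------------------------------------------------

    def as_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((v.node_a, v.node_b, {"vessel": v.id}) for v in self.vessels.values())
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    def is_tree(self) -> bool:
        return self.n_vessels == self.n_nodes - 1

    def terminal_node_ids(self) -> List[int]:
        return [nid for nid in self.nodes if self.nodes[nid].kind == "terminal"]

    def children(self, vessel_id: int) -> List[int]:
        """Vessel ids leaving the distal node of ``vessel_id`` (trees)."""
        v = self.vessels[vessel_id]
        return [w for w in self.adjacency[v.node_b] if self.vessels[w].node_a == v.node_b]

    def outgoing(self, node_id: int) -> List[int]:
        return [w for w in self.adjacency[node_id] if self.vessels[w].node_a == node_id]

    def require_rooted_tree(self) -> None:
        if self.root_id is None or not self.is_tree():
            raise UnsupportedTopologyError(
                "operation requires a rooted tree (networks with loops are not "
                "supported; a pressure-based hierarchy would be needed)"
            )
        # every non-root node must have exactly one incoming vessel
        incoming: Dict[int, int] = {}
        for v in self.vessels.values():
            incoming[v.node_b] = incoming.get(v.node_b, 0) + 1
        for nid in self.nodes:
            expect = 0 if nid == self.root_id else 1
            if incoming.get(nid, 0) != expect:
                raise UnsupportedTopologyError(
                    f"node {nid} has {incoming.get(nid, 0)} incoming vessels; "
                    "flow orientation does not define a rooted tree"
                )

    def total_length(self) -> float:
        return sum(v.length for v in self.vessels.values())

    def vessel_array(self, attr: str) -> np.ndarray:
        """Per-vessel attribute as an array ordered by sorted vessel id."""
        ids = sorted(self.vessels)
        return np.array([getattr(self.vessels[i], attr) for i in ids])

    def sorted_vessel_ids(self) -> List[int]:
        return sorted(self.vessels)


@dataclass
class HierarchicField:
    """Normalised distal-length hierarchy: 1 at the root, 0 at terminals."""

    zeta_node: Dict[int, float]
    zeta_vessel: Dict[int, float]


@dataclass
class PartitionVector:
    """Ordered vector Z of N+1 strictly decreasing values, Z[0]=1, Z[N]=0."""

    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 1 or self.Z.size < 2:
            raise ValueError("Z must have at least two entries")
        if self.Z[0] != 1.0 or self.Z[-1] != 0.0:
            raise ValueError("Z must start at 1 and end at 0")
        if not np.all(np.diff(self.Z) < 0):
            raise ValueError("Z must be strictly decreasing")

    @property
    def n_compartments(self) -> int:
        return self.Z.size - 1


# -- file I/O -----------------------------------------------------------------

NODE_COLUMNS = ["id", "x", "y", "z", "radius"]
EDGE_COLUMNS = ["id", "node_a", "node_b"]


def read_network(path: str | Path) -> VascularNetwork:
    """Read ``nodes.csv`` / ``edges.csv`` from directory ``path``.

    Node columns: id, x, y, z, radius.  Edge columns: id, node_a, node_b and
    optionally compartment and flux.  Ids are integers; coordinates and radii
    are in mm.
    """
    path = Path(path)
    nodes_file = path / "nodes.csv"
    edges_file = path / "edges.csv"
    for f in (nodes_file, edges_file):
        if not f.exists():
            raise FileNotFoundError(f)
    ndf = pd.read_csv(nodes_file, float_precision="round_trip")
    edf = pd.read_csv(edges_file, float_precision="round_trip")
    missing = [c for c in NODE_COLUMNS if c not in ndf.columns]
    if missing:
        raise NetworkValidationError(f"nodes.csv missing columns {missing}")
    missing = [c for c in EDGE_COLUMNS if c not in edf.columns]
    if missing:
        raise NetworkValidationError(f"edges.csv missing columns {missing}")
    nodes = [
        VesselNode(int(r.id), np.array([r.x, r.y, r.z]), float(r.radius))
        for r in ndf.itertuples()
    ]
    vessels = []
    for r in edf.itertuples():
        v = Vessel(int(r.id), int(r.node_a), int(r.node_b))
        if "compartment" in edf.columns and not pd.isna(r.compartment):
            v.compartment = int(r.compartment)
        if "flux" in edf.columns and not pd.isna(r.flux):
            v.flux = float(r.flux)
        vessels.append(v)
    root_id = None
    if "kind" in ndf.columns:
        roots = ndf.loc[ndf["kind"] == "root", "id"]
        if len(roots) == 1:
            root_id = int(roots.iloc[0])
    return VascularNetwork(nodes, vessels, root_id=root_id)


def write_network(network: VascularNetwork, path: str | Path) -> None:
    """Write the network as ``nodes.csv`` / ``edges.csv`` under ``path``.

    Lossless for ids, positions, radii, node kinds, compartments and fluxes
    (full float precision).
    """
    if not network.vessels:
        raise NetworkValidationError("refusing to write a network with no vessels")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nids = sorted(network.nodes)
    ndf = pd.DataFrame(
        {
            "id": nids,
            "x": [network.nodes[i].position[0] for i in nids],
            "y": [network.nodes[i].position[1] for i in nids],
            "z": [network.nodes[i].position[2] for i in nids],
            "radius": [network.nodes[i].radius for i in nids],
            "kind": [network.nodes[i].kind for i in nids],
        }
    )
    vids = network.sorted_vessel_ids()
    edf = pd.DataFrame(
        {
            "id": vids,
            "node_a": [network.vessels[i].node_a for i in vids],
            "node_b": [network.vessels[i].node_b for i in vids],
            "compartment": [network.vessels[i].compartment for i in vids],
            "flux": [network.vessels[i].flux for i in vids],
        }
    )
    ndf.to_csv(path / "nodes.csv", index=False, float_format="%.17g")
    edf.to_csv(path / "edges.csv", index=False, float_format="%.17g")


# -- hierarchic parameter -----------------------------------------------------


def compute_zeta(network: VascularNetwork) -> HierarchicField:
    """Normalised distal-length hierarchy for a rooted tree.

    ``zeta`` at a node is the sum of the lengths of all vessels distal to the
    node divided by the total vessel length; the root has ``zeta = 1`` and
    distal terminals have ``zeta = 0``.  The per-vessel value is the mean of
    its endpoint nodal values.
    """
    network.require_rooted_tree()
    total = network.total_length()
    # iterative post-order accumulation of distal subtree length per node
    distal: Dict[int, float] = {}
    order: List[int] = []
    stack = [network.root_id]
    seen = set()
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise UnsupportedTopologyError("cycle detected while traversing tree")
        seen.add(nid)
        order.append(nid)
        for w in network.outgoing(nid):
            stack.append(network.vessels[w].node_b)
    for nid in reversed(order):
        s = 0.0
        for w in network.outgoing(nid):
            v = network.vessels[w]
            s += v.length + distal[v.node_b]
        distal[nid] = s
    zeta_node = {nid: distal[nid] / total for nid in network.nodes}
    zeta_vessel = {
        vid: 0.5 * (zeta_node[v.node_a] + zeta_node[v.node_b])
        for vid, v in network.vessels.items()
    }
    return HierarchicField(zeta_node=zeta_node, zeta_vessel=zeta_vessel)


def _labels_for_z(zbar: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Compartment labels (1-based) for per-vessel zeta values given Z.

    Compartment ``i`` covers ``[Z[i], Z[i-1])`` with the descending stored Z;
    a value of exactly 1 belongs to compartment 1.
    """
    # np.searchsorted on the descending Z: find first interval whose lower
    # bound <= zbar.  Work on the ascending reversed array instead.
    asc = Z[::-1]  # [0, ..., 1]
    # index j such that asc[j] <= z < asc[j+1]  -> compartment N - j
    j = np.searchsorted(asc, zbar, side="right") - 1
    n = Z.size - 1
    labels = n - j
    labels[zbar >= 1.0] = 1
    return labels.astype(int)


def partition_by_zeta(
    network: VascularNetwork, hier: HierarchicField, Z: PartitionVector
) -> Dict[int, int]:
    """Label every vessel with its compartment (1-based) and return the map.

    Vessel v is placed in compartment i iff its average zeta lies in
    ``[Z[i], Z[i-1])``; an average of exactly 1 goes to compartment 1.
    Labels are also stored on ``network.vessels[*].compartment``.
    """
    vids = network.sorted_vessel_ids()
    zbar = np.array([hier.zeta_vessel[i] for i in vids])
    labels = _labels_for_z(zbar, Z.Z)
    out = {}
    for vid, lab in zip(vids, labels):
        network.vessels[vid].compartment = int(lab)
        out[vid] = int(lab)
    return out


def _partition_cost(
    sorted_desc_zbar: np.ndarray,
    prefix_radius: np.ndarray,
    thresholds: Sequence[float],
    targets: np.ndarray,
) -> float:
    """RMS of (compartment mean radius - target) for interior thresholds.

    ``sorted_desc_zbar`` is zeta-bar sorted descending; ``prefix_radius`` is
    the prefix sum of the correspondingly sorted radii with a leading 0.
    Empty compartments cost infinity.
    """
    n = targets.size
    cuts = [0]
    for t in thresholds:
        # vessels with zbar >= t are above the cut (they belong to earlier cpts)
        cuts.append(int(np.searchsorted(-sorted_desc_zbar, -t, side="right")))
    cuts.append(sorted_desc_zbar.size)
    sq = 0.0
    for i in range(n):
        lo, hi = cuts[i], cuts[i + 1]
        if hi <= lo:
            return float("inf")
        mean = (prefix_radius[hi] - prefix_radius[lo]) / (hi - lo)
        sq += (mean - targets[i]) ** 2
    return math.sqrt(sq / n)


def default_partition_targets(
    network: VascularNetwork, fractions: Sequence[float] = (0.04, 0.46, 0.50)
) -> Tuple[float, ...]:
    """Target compartment mean radii derived from the radius distribution.

    Splits the vessels by radius rank into blocks of the given fractions
    (proximal arterial block small, the two distal blocks sharing the rest,
    mirroring typical arteriolar/capillary proportions) and returns each
    block's mean radius.  Used when no explicit targets are supplied, so the
    partition adapts to the scale range of the network at hand.
    """
    radii = np.sort(network.vessel_array("radius"))[::-1]
    bounds = np.cumsum(np.asarray(fractions) / np.sum(fractions)) * radii.size
    bounds = np.clip(np.round(bounds).astype(int), 1, radii.size)
    targets = []
    lo = 0
    for hi in bounds:
        hi = max(hi, lo + 1)
        targets.append(float(radii[lo:hi].mean()))
        lo = hi
    # enforce strict decrease for degenerate distributions
    for i in range(1, len(targets)):
        if targets[i] >= targets[i - 1]:
            targets[i] = targets[i - 1] * (1 - 1e-9)
    return tuple(targets)


def optimise_partition(
    network: VascularNetwork,
    hier: HierarchicField,
    target_mean_radii: Sequence[float],
    coarse: int = 150,
) -> PartitionVector:
    """Find Z minimising the rms mismatch of compartment mean radii.

    Deterministic: a coarse grid over candidate thresholds (drawn from the
    observed per-vessel zeta values) followed by coordinate-wise refinement
    over all candidates; ties break toward larger Z entries.
    """
    targets = np.asarray(target_mean_radii, dtype=float)
    n = targets.size
    if n == 1:
        return PartitionVector(np.array([1.0, 0.0]))
    if n >= 2 and not np.all(np.diff(targets) < 0):
        raise ValueError("target mean radii must be strictly decreasing")
    vids = network.sorted_vessel_ids()
    zbar = np.array([hier.zeta_vessel[i] for i in vids])
    radii = np.array([network.vessels[i].radius for i in vids])
    uniq = np.unique(zbar)
    if uniq.size < n:
        raise InfeasiblePartitionError(
            f"only {uniq.size} distinct zeta values for {n} compartments"
        )
    order = np.argsort(-zbar, kind="stable")
    zdesc = zbar[order]
    prefix = np.concatenate([[0.0], np.cumsum(radii[order])])
    # candidate thresholds: the distinct zeta values (cutting at a datum puts
    # it in the lower-index compartment via the bottom-closed interval) minus
    # the extremes, which cannot separate anything
    cands = uniq[(uniq > uniq[0]) & (uniq < 1.0)]
    if cands.size == 0:
        cands = uniq[:-1]
    step = max(1, cands.size // coarse)
    coarse_cands = cands[::step]

    def cost(ths: Sequence[float]) -> float:
        return _partition_cost(zdesc, prefix, ths, targets)

    # coarse search: greedy nested loops are exponential for general N; use
    # full grid for N=2,3 (the practical cases), greedy refinement otherwise
    best: Tuple[float, Tuple[float, ...]] = (float("inf"), ())
    if n == 2:
        for t in coarse_cands:
            c = cost((t,))
            if c < best[0] - 1e-15 or (abs(c - best[0]) <= 1e-15 and (t,) > best[1]):
                best = (c, (float(t),))
    elif n == 3:
        for i, t1 in enumerate(coarse_cands):
            for t2 in coarse_cands[:i]:
                c = cost((t1, t2))
                cand = (float(t1), float(t2))
                if c < best[0] - 1e-15 or (abs(c - best[0]) <= 1e-15 and cand > best[1]):
                    best = (c, cand)
    else:
        # even quantile start
        qs = np.linspace(1, 0, n + 1)[1:-1]
        ths = tuple(float(np.quantile(cands, q)) for q in qs)
        best = (cost(ths), ths)
    # coordinate-wise refinement over the full candidate list
    ths = list(best[1])
    improved = True
    while improved:
        improved = False
        for k in range(len(ths)):
            hi = ths[k - 1] if k > 0 else 1.0
            lo = ths[k + 1] if k + 1 < len(ths) else 0.0
            for t in cands[(cands < hi) & (cands > lo)]:
                trial = ths.copy()
                trial[k] = float(t)
                c = cost(trial)
                if c < best[0] - 1e-15 or (
                    abs(c - best[0]) <= 1e-15 and tuple(trial) > tuple(ths)
                ):
                    best = (c, tuple(trial))
                    ths = trial.copy()
                    improved = True
    if not np.isfinite(best[0]):
        raise InfeasiblePartitionError("no feasible partition found")
    return PartitionVector(np.array([1.0, *best[1], 0.0]))
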