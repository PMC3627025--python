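"""Seeded generators for synthetic vascular networks.

Two generators are provided:

* a bifurcating volume-filling tree on an axis-aligned box, built by
  recursive alternating-axis bisection (each subdomain contributes one
  jittered bifurcation point), with mass-conserving flux assignment and a
  power-law flux-radius relation;
* an anisotropic capillary lattice of near-parallel fibres with sparse
  cross-links, standing in for imaged capillary beds with a preferred
  direction.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import (
    NetworkValidationError,
    UnsupportedTopologyError,
    Vessel,
    VesselNode,
    VascularNetwork,
)

__all__ = [
    "GeneratorConfig",
    "generate_volume_filling_tree",
    "assign_fluxes",
    "flux_to_radius",
    "assign_radii",
    "generate_aligned_lattice",
    "generate_isotropic_lattice",
    "monte_carlo_volume",
]

DEFAULT_DOMAIN = np.array([[-1.0, 1.0], [-1.0, 1.0], [-1.0, 1.0]])
DEFAULT_ALPHA = (1.0, 3.0, 0.001)


@dataclass
class GeneratorConfig:
    """Configuration of the volume-filling tree generator.

    ``alpha = (a1, a2, a3)`` are the parameters of the flux-radius relation
    ``r = (q / a1) ** (1 / a2) * a3`` (defaults 1, 3, 0.001 give radii in mm
    for unit terminal fluxes).  ``jitter`` perturbs each bifurcation point by
    a uniform fraction of the local subdomain half-size.
    """

    domain: np.ndarray = field(default_factory=lambda: DEFAULT_DOMAIN.copy())
    levels: int = 8
    seed: int = 0
    alpha: Tuple[float, float, float] = DEFAULT_ALPHA
    jitter: float = 0.3

    def __post_init__(self) -> None:
        self.domain = np.asarray(self.domain, dtype=float)
        if self.domain.shape != (3, 2) or np.any(self.domain[:, 1] <= self.domain[:, 0]):
            raise ValueError("domain must be a non-degenerate (3, 2) box")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        a1, a2, a3 = self.alpha
        if a2 == 0 or a3 <= 0:
            raise ValueError("alpha must satisfy a2 != 0, a3 > 0")
        if not (0 <= self.jitter < 1):
            raise ValueError("jitter must be in [0, 1)")
        # each axis is halved roughly every third level
        min_size = np.min(self.domain[:, 1] - self.domain[:, 0]) * 0.5 ** math.ceil(
            self.levels / 3
        )
        if min_size < 1e-9:
            raise ValueError("levels too large: subdomain size underflows")


def generate_volume_filling_tree(config: GeneratorConfig) -> VascularNetwork:
    """Rooted binary tree whose terminals fill the configured box.

    The box is recursively bisected along alternating axes; each subdomain
    receives one bifurcation point at its jittered centroid.  The root node
    sits at the centre of the low-x face and feeds the first bifurcation
    point.  ``levels = L`` produces ``2**L`` terminals and ``2**(L+1) - 1``
    vessels.  Fluxes and radii are assigned on the returned network.
    """
    rng = np.random.default_rng(config.seed)
    box = config.domain
    nodes: List[VesselNode] = []
    vessels: List[Vessel] = []

    def centroid(b: np.ndarray) -> np.ndarray:
        c = b.mean(axis=1)
        half = 0.5 * (b[:, 1] - b[:, 0])
        return c + config.jitter * half * rng.uniform(-1.0, 1.0, size=3)

    def new_node(pos: np.ndarray) -> int:
        nid = len(nodes)
        nodes.append(VesselNode(nid, pos, radius=1.0))  # radii assigned later
        return nid

    root_pos = np.array([box[0, 0], box[1].mean(), box[2].mean()])
    root_id = new_node(root_pos)

    def subdivide(parent: int, b: np.ndarray, axis: int, depth: int) -> None:
        point = new_node(centroid(b))
        vessels.append(Vessel(len(vessels), parent, point))
        if depth < config.levels:
            mid = b[axis].mean()
            lo, hi = b.copy(), b.copy()
            lo[axis, 1] = mid
            hi[axis, 0] = mid
            nxt = (axis + 1) % 3
            subdivide(point, lo, nxt, depth + 1)
            subdivide(point, hi, nxt, depth + 1)

    # the first bifurcation point sits in the full box; its two children are
    # bisection generation 1, so `depth` counts bisection generations
    first = new_node(centroid(box))
    vessels.append(Vessel(0, root_id, first))
    mid = box[0].mean()
    lo, hi = box.copy(), box.copy()
    lo[0, 1] = mid
    hi[0, 0] = mid
    subdivide(first, lo, 1, 1)
    subdivide(first, hi, 1, 1)

    net = VascularNetwork(nodes, vessels, root_id=root_id)
    assign_fluxes(net)
    assign_radii(net, config.alpha)
    return net


def assign_fluxes(network: VascularNetwork) -> Dict[int, float]:
    """Mass-conserving fluxes: terminal vessels carry 1, parents sum daughters.

    Returns the vessel-id -> flux map (also stored on the vessels).  Fluxes
    are in mm^3/s with the unit terminal flow taken as 1 mm^3/s.
    """
    network.require_rooted_tree()
    flux: Dict[int, float] = {}
    # post-order over vessels
    order: List[int] = []
    stack = list(network.outgoing(network.root_id))
    while stack:
        vid = stack.pop()
        order.append(vid)
        stack.extend(network.children(vid))
    for vid in reversed(order):
        kids = network.children(vid)
        flux[vid] = 1.0 if not kids else sum(flux[k] for k in kids)
        network.vessels[vid].flux = flux[vid]
    return flux


def flux_to_radius(q: np.ndarray | float, alpha: Sequence[float] = DEFAULT_ALPHA) -> np.ndarray | float:
    """Power-law flux-radius relation r = (q / a1) ** (1 / a2) * a3 (mm)."""
    a1, a2, a3 = alpha
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("fluxes must be positive")
    r = (q / a1) ** (1.0 / a2) * a3
    return float(r) if r.ndim == 0 else r


def assign_radii(
    network: VascularNetwork, alpha: Sequence[float] = DEFAULT_ALPHA
) -> Dict[int, float]:
    """Assign radii from vessel fluxes via the flux-radius relation.

    Each vessel gets a relation radius from its flux; each node inherits the
    relation radius of its proximal (incoming) vessel, the root node that of
    the root vessel.  Vessel radii are then re-derived as the mean of their
    endpoint nodal radii (the convention also used when reading networks from
    file).  Returns the per-vessel relation radii.
    """
    network.require_rooted_tree()
    rel: Dict[int, float] = {}
    for vid, v in network.vessels.items():
        if not np.isfinite(v.flux):
            raise ValueError(f"vessel {vid} has no flux; run assign_fluxes first")
        rel[vid] = float(flux_to_radius(v.flux, alpha))
    for vid, v in network.vessels.items():
        network.nodes[v.node_b].radius = rel[vid]
    root_vessels = network.outgoing(network.root_id)
    network.nodes[network.root_id].radius = rel[root_vessels[0]]
    for v in network.vessels.values():
        v.radius = 0.5 * (
            network.nodes[v.node_a].radius + network.nodes[v.node_b].radius
        )
    return rel


# -- anisotropic lattice ------------------------------------------------------


def _truncated_normal_radii(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    r = rng.normal(mean, sd, size=n)
    floor = max(mean / 10.0, 1e-4)
    return np.clip(r, floor, None)


def generate_aligned_lattice(
    domain: np.ndarray = DEFAULT_DOMAIN,
    direction: Sequence[float] = (1.0, 0.0, 0.0),
    n_fibres: int = 25,
    cross_link_fraction: float = 0.15,
    radius_mean: float = 0.0053,
    radius_sd: float = 0.0023,
    seed: int = 0,
    n_segments: int = 8,
    jitter: float = 0.25,
) -> VascularNetwork:
    """Near-parallel capillary fibres along ``direction`` with sparse links.

    A synthetic stand-in for imaged capillary networks with a preferred
    vessel direction (radii drawn from a clipped normal, defaults 5.3 +/- 2.3
    um).  Fibres run face to face along the dominant axis of ``direction``
    (axis-aligned directions supported); each pair of transversally adjacent
    fibres is anastomosed at one random interior rung with probability
    ``cross_link_fraction`` (anastomoses are sparse relative to fibre
    length, as in aligned capillary beds).  The output is re-linked if
    disconnected, so it is always a single connected component, with
    terminal nodes exposed on the two faces normal to the fibre axis.
    """
    if n_fibres < 1:
        raise ValueError("n_fibres must be >= 1")
    domain = np.asarray(domain, dtype=float)
    axis = int(np.argmax(np.abs(np.asarray(direction, dtype=float))))
    t_axes = [a for a in range(3) if a != axis]
    rng = np.random.default_rng(seed)

    # transverse fibre anchor positions on a jittered grid
    m = max(1, int(math.ceil(math.sqrt(n_fibres))))
    anchors = []
    for i in range(m):
        for j in range(m):
            if len(anchors) >= n_fibres:
                break
            u = (i + 0.5) / m
            w = (j + 0.5) / m
            anchors.append((u, w))
    lo, hi = domain[:, 0], domain[:, 1]
    span_t = [hi[a] - lo[a] for a in t_axes]

    nodes: List[VesselNode] = []
    vessels: List[Vessel] = []
    node_grid: Dict[Tuple[int, int], int] = {}

    def new_node(pos: np.ndarray, radius: float) -> int:
        nid = len(nodes)
        nodes.append(VesselNode(nid, pos, radius))
        return nid

    radii = _truncated_normal_radii(
        rng, n_fibres * (n_segments + 1), radius_mean, radius_sd
    )
    k = 0
    for f, (u, w) in enumerate(anchors):
        for s in range(n_segments + 1):
            pos = np.empty(3)
            pos[axis] = lo[axis] + (hi[axis] - lo[axis]) * s / n_segments
            base = [lo[t_axes[0]] + u * span_t[0], lo[t_axes[1]] + w * span_t[1]]
            for t, b, sp in zip(t_axes, base, span_t):
                jit = 0.0
                if 0 < s < n_segments:
                    jit = jitter * (sp / m) * rng.uniform(-0.5, 0.5)
                pos[t] = np.clip(b + jit, lo[t] + 1e-9, hi[t] - 1e-9)
            # faces stay exactly on the boundary along the fibre axis
            node_grid[(f, s)] = new_node(pos, radii[k])
            k += 1
        for s in range(n_segments):
            vessels.append(
                Vessel(len(vessels), node_grid[(f, s)], node_grid[(f, s + 1)])
            )

    # cross-links between transversally adjacent fibres at interior rungs
    def fibre_uv(f: int) -> Tuple[int, int]:
        return f // m, f % m

    neighbour_pairs = []
    for f in range(len(anchors)):
        i, j = fibre_uv(f)
        for di, dj in ((1, 0), (0, 1)):
            g = (i + di) * m + (j + dj)
            gi, gj = i + di, j + dj
            if gi < m and gj < m and g < len(anchors):
                neighbour_pairs.append((f, g))
    for f, g in neighbour_pairs:
        if rng.uniform() < cross_link_fraction:
            s = int(rng.integers(1, max(2, n_segments)))
            vessels.append(
                Vessel(len(vessels), node_grid[(f, s)], node_grid[(g, s)])
            )

    # re-link disconnected components (minimal extra rungs)
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for v in vessels:
        union(v.node_a, v.node_b)
    if len(anchors) > 1:
        mid = n_segments // 2
        for f, g in neighbour_pairs:
            a, b = node_grid[(f, mid)], node_grid[(g, mid)]
            if find(a) != find(b):
                vessels.append(Vessel(len(vessels), a, b))
                union(a, b)
        # fall back to chaining fibres in index order (covers sparse anchors)
        for f in range(len(anchors) - 1):
            a, b = node_grid[(f, mid)], node_grid[(f + 1, mid)]
            if find(a) != find(b):
                vessels.append(Vessel(len(vessels), a, b))
                union(a, b)
    roots = {find(x) for x in range(len(nodes))}
    if len(roots) != 1:
        raise NetworkValidationError("lattice generator produced a disconnected network")
    return VascularNetwork(nodes, vessels, root_id=node_grid[(0, 0)])


def generate_isotropic_lattice(
    domain: np.ndarray = DEFAULT_DOMAIN,
    n_fibres: int = 25,
    cross_link_fraction: float = 0.15,
    radius_mean: float = 0.0053,
    radius_sd: float = 0.0023,
    seed: int = 0,
    n_segments: int = 8,
) -> VascularNetwork:
    """Isotropic control: three orthogonal fibre families merged and linked."""
    nets = [
        generate_aligned_lattice(
            domain,
            direction=np.eye(3)[a],
            n_fibres=n_fibres,
            cross_link_fraction=cross_link_fraction,
            radius_mean=radius_mean,
            radius_sd=radius_sd,
            seed=seed + a,
            n_segments=n_segments,
        )
        for a in range(3)
    ]
    nodes: List[VesselNode] = []
    vessels: List[Vessel] = []
    for net in nets:
        off = len(nodes)
        voff = len(vessels)
        for nid in sorted(net.nodes):
            n = net.nodes[nid]
            nodes.append(VesselNode(off + nid, n.position.copy(), n.radius))
        for vid in net.sorted_vessel_ids():
            v = net.vessels[vid]
            vessels.append(Vessel(voff + vid, off + v.node_a, off + v.node_b))
    # stitch the three families: join each family to the next at the nearest
    # node pair (computed over a seeded subsample for determinism and speed)
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    offsets = np.cumsum([0] + [n.n_nodes for n in nets])
    pos = np.array([n.position for n in nodes])
    for a in range(2):
        ia = np.arange(offsets[a], offsets[a + 1])
        ib = np.arange(offsets[a + 1], offsets[a + 2])
        tree = cKDTree(pos[ib])
        sub = rng.choice(ia, size=min(64, ia.size), replace=False)
        d, j = tree.query(pos[sub])
        # several stitches so the families exchange flow in more than one spot
        order = np.argsort(d)[:4]
        for o in order:
            vessels.append(Vessel(len(vessels), int(sub[o]), int(ib[j[o]])))
    return VascularNetwork(nodes, vessels, root_id=0)


def monte_carlo_volume(
    region: Callable[[np.ndarray], np.ndarray],
    box: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Monte Carlo volume of ``region`` within ``box``: (estimate, std error).

    ``region`` maps an (n, 3) array of points to a boolean mask.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(box[:, 0], box[:, 1], size=(n_samples, 3))
    hits = np.asarray(region(pts), dtype=bool)
    p = hits.mean()
    vol_box = float(np.prod(box[:, 1] - box[:, 0]))
    est = p * vol_box
    se = vol_box * math.sqrt(max(p * (1 - p), 0.0) / n_samples)
    return est, se
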