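"""Discrete Poiseuille flow on a vascular network.

Each vessel is a Poiseuille tube: ``Q = C (p_a - p_b)`` with conductance
``C = pi r^4 / (8 mu l)`` (equivalently ``pi d^4 / (128 mu l)`` in terms of
the diameter).  Mass conservation at every junction turns the network into a
weighted graph Laplacian system for the nodal pressures, solved sparsely
with Dirichlet pressures eliminated.  Terminals without a Dirichlet value
are treated as zero-flux (free) nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VascularNetwork

__all__ = [
    "DEFAULT_VISCOSITY",
    "poiseuille_conductance",
    "build_incidence",
    "solve_network_flow",
    "NetworkFlowSolution",
]

#: blood dynamic viscosity, Pa s
DEFAULT_VISCOSITY = 0.0035


def poiseuille_conductance(r, l, mu: float = DEFAULT_VISCOSITY):
    """Poiseuille conductance pi r^4 / (8 mu l) in mm^3 Pa^-1 s^-1."""
    r = np.asarray(r, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(r <= 0) or np.any(l <= 0) or mu <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    c = np.pi * r**4 / (8.0 * mu * l)
    return float(c) if c.ndim == 0 else c


def build_incidence(network: VascularNetwork) -> sp.csr_matrix:
    """Signed incidence over internal nodes: +1 incoming, -1 outgoing.

    Rows are internal nodes in sorted-id order, columns are vessels in
    sorted-id order.  Terminal and root nodes contribute no row, so
    ``L @ Q = 0`` expresses junction mass conservation.
    """
    internal = [
        nid for nid in sorted(network.nodes) if network.nodes[nid].kind == "internal"
    ]
    row_of = {nid: i for i, nid in enumerate(internal)}
    vids = network.sorted_vessel_ids()
    col_of = {vid: j for j, vid in enumerate(vids)}
    rows, cols, vals = [], [], []
    for vid in vids:
        v = network.vessels[vid]
        if v.node_b in row_of:  # incoming to node_b
            rows.append(row_of[v.node_b])
            cols.append(col_of[vid])
            vals.append(1.0)
        if v.node_a in row_of:  # outgoing from node_a
            rows.append(row_of[v.node_a])
            cols.append(col_of[vid])
            vals.append(-1.0)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(internal), len(vids))
    )


@dataclass
class NetworkFlowSolution:
    """Nodal pressures (Pa) and signed vessel fluxes (mm^3/s, along a->b)."""

    pressure: Dict[int, float]
    flux: Dict[int, float]
    mu: float
    mass_residual: float  # max |sum of fluxes| over free nodes

    def pressure_array(self, network: VascularNetwork) -> np.ndarray:
        return np.array([self.pressure[i] for i in sorted(network.nodes)])

    def flux_array(self, network: VascularNetwork) -> np.ndarray:
        return np.array([self.flux[i] for i in network.sorted_vessel_ids()])


def solve_network_flow(
    network: VascularNetwork,
    dirichlet: Mapping[int, float],
    mu: float = DEFAULT_VISCOSITY,
) -> NetworkFlowSolution:
    """Solve nodal pressures with Dirichlet terminal pressures (Pa).

    Every node not in ``dirichlet`` is a free (zero net flux) unknown; this
    covers both junctions and zero-flux terminals.  The symmetric positive
    definite reduced Laplacian is solved by a sparse direct factorisation.
    """
    if not dirichlet:
        raise ValueError("at least one Dirichlet pressure is required")
    for nid in dirichlet:
        if nid not in network.nodes:
            raise ValueError(f"Dirichlet node {nid} not in network")
    nids = sorted(network.nodes)
    idx = {nid: i for i, nid in enumerate(nids)}
    n = len(nids)
    vids = network.sorted_vessel_ids()
    a = np.array([idx[network.vessels[v].node_a] for v in vids])
    b = np.array([idx[network.vessels[v].node_b] for v in vids])
    r = network.vessel_array("radius")
    l = network.vessel_array("length")
    c = poiseuille_conductance(r, l, mu)

    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([a, b, b, a])
    vals = np.concatenate([c, c, -c, -c])
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    fixed = np.zeros(n, dtype=bool)
    p = np.zeros(n)
    for nid, val in dirichlet.items():
        fixed[idx[nid]] = True
        p[idx[nid]] = float(val)
    free = ~fixed
    if free.any():
        a_ff = lap[free][:, free].tocsc()
        rhs = -lap[free][:, fixed] @ p[fixed]
        try:
            p[free] = spla.spsolve(a_ff, rhs)
        except RuntimeError as exc:  # singular: disconnected free block
            raise ValueError(
                "singular pressure system: a connected component has no "
                "Dirichlet pressure"
            ) from exc
        if not np.all(np.isfinite(p)):
            raise ValueError(
                "singular pressure system: a connected component has no "
                "Dirichlet pressure"
            )

    q = c * (p[a] - p[b])
    net_flux = np.zeros(n)
    np.subtract.at(net_flux, a, q)
    np.add.at(net_flux, b, q)
    resid = float(np.max(np.abs(net_flux[free]))) if free.any() else 0.0
    return NetworkFlowSolution(
        pressure={nid: float(p[idx[nid]]) for nid in nids},
        flux={vid: float(qv) for vid, qv in zip(vids, q)},
        mu=mu,
        mass_residual=resid,
    )
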