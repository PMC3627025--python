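"""Legacy-ASCII VTK writers for networks and grid fields.

Structured grids carry nodal scalar fields and 3x3 symmetric tensor fields
(as six-component arrays xx yy zz xy xz yz); networks are written as
polydata polylines with per-point radius/pressure and per-cell attributes.
Legacy VTK orders structured points x-fastest, whereas the package's grid
arrays are x-slowest (C order over (i, j, k)); the writers transpose.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np

from .fem import GridMesh
from .network import VascularNetwork

__all__ = ["write_structured_grid", "write_network_polydata"]


def _grid_to_vtk_order(values: np.ndarray, shape) -> np.ndarray:
    return np.asarray(values).reshape(shape).transpose(2, 1, 0).ravel()


def write_structured_grid(
    path: str | Path,
    mesh: GridMesh,
    point_scalars: Optional[Mapping[str, np.ndarray]] = None,
    point_tensors: Optional[Mapping[str, np.ndarray]] = None,
) -> None:
    """Write nodal fields on the uniform mesh as legacy VTK STRUCTURED_POINTS."""
    path = Path(path)
    m = mesh.n + 1
    origin = mesh.box[:, 0]
    h = mesh.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        "darcyparam structured grid",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {m} {m} {m}",
        f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}",
        f"SPACING {h[0]:.9g} {h[1]:.9g} {h[2]:.9g}",
        f"POINT_DATA {m**3}",
    ]
    for name, vals in (point_scalars or {}).items():
        data = _grid_to_vtk_order(vals, mesh.shape)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in data)
    for name, K in (point_tensors or {}).items():
        K = np.asarray(K)
        comps = np.column_stack(
            [K[:, 0, 0], K[:, 1, 1], K[:, 2, 2], K[:, 0, 1], K[:, 0, 2], K[:, 1, 2]]
        )
        reordered = np.column_stack(
            [_grid_to_vtk_order(comps[:, c], mesh.shape) for c in range(6)]
        )
        lines.append(f"FIELD FieldData 1")
        lines.append(f"{name} 6 {m**3} double")
        lines.extend(" ".join(f"{v:.9g}" for v in row) for row in reordered)
    path.write_text("\n".join(lines) + "\n")


def write_network_polydata(
    path: str | Path,
    network: VascularNetwork,
    point_data: Optional[Mapping[str, Mapping[int, float]]] = None,
    cell_data: Optional[Mapping[str, Mapping[int, float]]] = None,
) -> None:
    """Write the network centrelines as legacy VTK polydata lines."""
    path = Path(path)
    nids = sorted(network.nodes)
    row = {nid: i for i, nid in enumerate(nids)}
    vids = network.sorted_vessel_ids()
    lines = [
        "# vtk DataFile Version 3.0",
        "darcyparam vascular network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(nids)} double",
    ]
    for nid in nids:
        p = network.nodes[nid].position
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append(f"LINES {len(vids)} {3 * len(vids)}")
    for vid in vids:
        v = network.vessels[vid]
        lines.append(f"2 {row[v.node_a]} {row[v.node_b]}")
    pdata = {"radius": {nid: network.nodes[nid].radius for nid in nids}}
    if point_data:
        pdata.update(point_data)
    lines.append(f"POINT_DATA {len(nids)}")
    for name, vals in pdata.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(vals[nid]):.9g}" for nid in nids)
    cdata: Dict[str, Dict[int, float]] = {}
    if cell_data:
        cdata.update({k: dict(v) for k, v in cell_data.items()})
    if any(v.compartment is not None for v in network.vessels.values()):
        cdata.setdefault(
            "compartment",
            {vid: float(network.vessels[vid].compartment or 0) for vid in vids},
        )
    if cdata:
        lines.append(f"CELL_DATA {len(vids)}")
        for name, vals in cdata.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(vals[vid]):.9g}" for vid in vids)
    path.write_text("\n".join(lines) + "\n")
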